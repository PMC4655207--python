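# perfseg

Regional cardiac-MR analysis of stress-induced ischemia and fibrosis in
hypertrophic cardiomyopathy (HCM), built around a synthetic short-axis
phantom cohort with known ground truth.

`perfseg` is aimed at imaging scientists who want a tested, reproducible
reference implementation of the classic *semiquantitative* first-pass
perfusion workflow: no absolute flow quantification, only the
maximum-upslope index that most clinical CMR perfusion studies report —
together with late-gadolinium-enhancement (LGE) scar quantification, AHA
segmentation, LVH/LGE tissue classification and nonparametric group
statistics.

## The model

For each myocardial region and physiologic state (rest, adenosine stress)
the signal-time curve `S(t)` of the first pass of a gadolinium bolus is
fitted by ordinary least squares in every contiguous window of `w` frames;
the steepest slope is the **maximum upslope**. Normalizing by the arterial
input function (AIF) in the LV blood pool and taking the stress/rest ratio
gives the **myocardial perfusion reserve index**:

    MPRI = (upslope_stress / AIF_stress) / (upslope_rest / AIF_rest)

Segments are the 16-segment AHA model (6 basal, 6 mid, 4 apical; apex
excluded), drawn on the myocardial annulus after contracting the
endo/epicardial contours by 10% transmurally to suppress partial-volume
contamination. Each segment is cross-classified as LVH± (end-diastolic
wall thickness > 13 mm in adults, thickness z-score > 3 against a
BSA-indexed normative table in pediatric subjects) and LGE± (scar
occupying ≥ 5% of the segment, scar = pixels above remote mean + 5 SD).
Classes are compared with the Kruskal–Wallis test and Dunn's post hoc
test; paired per-subject area comparisons (hypoperfused % of slice area at
rest and stress vs fibrotic %) use the Wilcoxon signed-rank test.

Because no public patient images exist for this protocol, the package
ships a first-class synthetic cohort generator: gamma-variate blood-pool
enhancement, myocardial curves with prescribed upslope transfer factors
(so MPRI has analytic ground truth), regional wall thickening, scar
nested inside hypoperfused hypertrophied sectors, and additive Gaussian
noise — all seeded and bit-reproducible.

## Worked example

```python
import perfseg as ps

cfg = ps.CohortConfig(seed=42)                      # 9 controls / 15 risk / 12 HCM
subjects = ps.generate_cohort(cfg)
res = ps.CohortPerfusionModel(subjects).fit()
print(res.summary())
```

```
Cohort analysis: 36 subjects (0 skipped)
========================================================
Segments analyzed: 576/576 (0 excluded)
  LVH-LGE-: n=516  upslope ratio 2.11 (1.63-2.65)
  LVH+LGE-: n=36  upslope ratio 1.44 (1.25-1.65)
  LVH+LGE+: n=24  upslope ratio 0.88 (0.77-1.02)
Tissue-class Kruskal-Wallis (segments): H=127.3, p=2.27e-28
  Dunn LVH-LGE- vs LVH+LGE-: z=8.04, p_adj=2.71e-15
  Dunn LVH-LGE- vs LVH+LGE+: z=9.24, p_adj=7.07e-20
  Dunn LVH+LGE- vs LVH+LGE+: z=2.05, p_adj=0.121
Areas (HCM, n=12): stress vs rest p=0.000488; stress vs LGE p=0.000488; stress >= LGE in all subjects: True
```

Reading this: perfusion reserve falls from normal (LVH−LGE−, median 2.11)
through hypertrophied non-fibrotic segments (1.44) to hypertrophied
fibrotic segments (0.88); hypoperfused area under stress exceeds the
fibrotic area in every HCM subject, consistent with ischemia preceding
fibrosis. (The last Dunn line illustrates a rank-test subtlety: with a
large reference class, the Bonferroni-adjusted contrast between the two
small classes is power-limited even under complete separation; see
`docs/methods.md`.)

Per-subject analysis and disk-based workflows:

```bash
perfseg simulate --seed 42 --out cohort/          # NIfTI + JSON + manifest
perfseg analyze  --subject cohort/ --id hcm_00
perfseg stats    --cohort cohort/ --out analysis/ # segments.csv, cohort_stats.csv
perfseg report   --subject cohort/ --id hcm_00 --out report/   # polar map
```

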