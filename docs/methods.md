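# Methods

This note documents the models, parameters and design choices behind
`perfseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Semiquantitative perfusion index

First-pass perfusion is summarized by the maximum upslope of the
signal-time curve. For a curve sampled at frames `t_i`, every contiguous
window of `window` frames (default 5) is fitted by ordinary least
squares; the steepest slope wins, ties broken by the earliest window. The
search interval ends two frames after the curve's global peak so that
recirculation upslopes are never selected; the fit window length and this
margin are configuration, since acquisition protocols differ. Curves are
baseline-corrected by subtracting the mean of the pre-contrast frames
(an additive shift that provably leaves every slope unchanged; it is kept
because it makes curves comparable for display and for the R² quality
gate). The tissue upslope is normalized by the AIF upslope measured in an
eroded blood-pool disc (50% of the mean endocardial radius) to avoid
papillary-muscle and partial-volume pixels, and the stress/rest ratio of
normalized upslopes is the perfusion reserve index (MPRI). No absolute
quantification (deconvolution, ml/g/min) is attempted: the index is
deliberately semiquantitative.

Quality control: a segment is excluded when the linear fit's R² falls
below 0.8 in either state (artefact surrogate) or when the rest/stress
segment masks overlap with Dice < 0.5 after slice matching (large
rest/stress mismatch). Both thresholds are configurable;
neither has a published reference value for this protocol.

## Geometry

Contours are simple polygons in pixel coordinates (x right, y down,
pixel centers at integer positions); angles are measured counterclockwise
on the displayed image. All angular operations — sector binning,
thickness rays, transmural contraction — are anchored on the
*endocardial* centroid: the cavity center is stable under regional wall
thickening, whereas the epicardial centroid shifts toward a hypertrophied
wall and would smear sector assignments.

The analyzed annulus is obtained by contracting the wall to transmural
depths [0.10, 0.90] along radial rays — a fractional (not fixed-mm)
contraction, so a 10% contraction means 10% of the local wall on every
ray. AHA sectors are 60° bins (basal, mid) and 90° bins rotated 45°
(apical) counterclockwise from the anterior RV insertion, with segment 1
(basal anterior) ending at the insertion ray; the AHA convention does not
fix the anchor, so it is recorded in the contour set. Sector masks
partition the annulus mask exactly by construction (every annulus pixel
is assigned to exactly one angular bin).

LV volumes and mass are planimetric: cavity/wall polygon areas times
slice thickness, mass at a myocardial density of 1.05 g/ml. Wall
thickness is the per-ray endo-epi distance; the interventricular-septum
and posterior-wall maxima are taken over configurable angular windows
(defaults 60–180° and 240–300° from the RV insertion) on the basal and
midventricular slices. Body surface area uses Mosteller by default
(DuBois optional).

Slice co-registration between cine, perfusion and LGE stacks is greedy
nearest-position pairing with a 5 mm tolerance; unmatched slices simply
drop out of segment scoring, mirroring incomplete acquisitions.

## LGE scar quantification

Scar is segmented per slice by remote-referenced thresholding: the remote
estimate starts from myocardial pixels below the myocardial median
intensity, is recomputed once after removing the provisional scar, and
the final threshold is remote mean + c·SD with c = 5. Connected
components below 10 pixels are discarded. Partial-volume weighting
(optional, on by default) credits each scar pixel a weight rising
linearly from 0 at the remote mean to 1 at the scar-core mean. The
mean+SD rule is invariant to affine intensity transforms, so no intensity
calibration is required. c, the minimum component size, and the
segment-level LGE+ criterion (scar ≥ 5% of segment pixels) are stated
choices exposed in configuration; manual corrections are out of scope and
replaced by an optional exclude-mask file.

## Tissue classification and statistics

Segments are cross-classified LVH± × LGE±. Adults (> 18 y) are LVH+ at
wall thickness > 13 mm; pediatric subjects use a thickness z-score > 3
against a BSA-indexed mean/SD lookup. The packaged normative table is
*synthetic* — a plausible monotone mean/SD-vs-BSA grid, not a published
pediatric reference — and must be replaced for any real-data use.

Group and class comparisons use the tie-corrected Kruskal–Wallis test
(chi-square p, k−1 df; the degenerate all-identical case returns H = 0,
p = 1) with Dunn's post hoc z from pooled mean ranks and tie-corrected
variance. Post hoc tests are only computed when the omnibus p is below
alpha. The default multiplicity adjustment is Bonferroni over the
k(k−1)/2 pairs.

One property of Dunn's test is worth recording: the z between two small
classes is computed on ranks pooled with every other class, so a large
reference class bounds the achievable mean-rank gap. With class sizes
132/36/24 the contrast between the two small classes cannot exceed
z ≈ 2.05 even under *complete* separation — Bonferroni-adjusted p ≈ 0.12,
unadjusted p ≈ 0.04. Evaluations of whether that contrast is "detected"
therefore use the unadjusted pairwise p; the adjusted value is reported
alongside.

Per-subject hypoperfused and fibrotic areas are paired observations, so
rest-vs-stress and stress-vs-LGE area comparisons default to the Wilcoxon
signed-rank test; an unpaired Kruskal–Wallis variant is retained behind a
flag for strict replication of rank-sum-only workflows. Per-patient
perfusion values are the arithmetic mean of a subject's non-excluded
segments per tissue class (median by flag).

## Synthetic cohort generator

The generator is the package's study design, not a test fixture. Each
subject contributes three short-axis slices (basal, mid, apical) on a
64×64 grid at 2 mm/pixel, 60 frames at 1 s intervals, bolus arrival at
10 s. Blood-pool enhancement is a peak-normalized gamma variate
(amplitude 1, shape 3, time constant 2 s) — the standard empirical
first-pass form. Tissue curves are the AIF enhancement scaled by a
transfer factor k (optionally delayed and boxcar-smoothed) rather than a
residue-function convolution: the analysis consumes only upslopes, and
this construction makes ground truth analytic — with unit smoothing and
integer-frame delay, max_upslope(tissue) = k·max_upslope(AIF) holds to
machine precision. Boxcar smoothing preserves the slope of a locally
linear rise, so k is still recovered when the bolus rise is long against
the kernel; a kernel comparable to the rise time attenuates the recovered
k, which is why the default smoothing width is 1.

Group structure (all editable in `perfseg/data/default_cohort.yaml`):
9 controls, 15 HCM-risk, 12 HCM. Rest transfer factor 0.5 everywhere;
stress/rest ratios 2.1 (controls), 2.2 (risk), and in HCM 2.0 for normal
sectors, 1.5 for hypertrophied non-fibrotic sectors, 0.9 for
scar-bearing sectors — calibrated to the class medians the analysis is
designed around. Per-subject multiplicative log-normal jitter (SD 0.08,
0.10 for risk) and small per-sector jitter (SD 0.03) provide biological
spread. HCM subjects carry 17 mm septal walls (anteroseptal and
inferoseptal at basal/mid, septal apical; plateau profile with cosine
ramps confined to the sector span) against 8 mm free walls; two of the
five hypertrophied sectors, chosen per subject, receive a mid-mural scar
wedge (central 60% of the sector's angle, transmural depth 0.3–0.7, so
the wedge survives the 10% contraction) and the severe stress reduction.
By construction scar ⊆ hypoperfused sectors ⊆ hypertrophied sectors;
controls and risk subjects have uniform perfusion, normal thickness and
no scar. LGE images put remote myocardium at 100 ± 5 and scar at
remote + 10 SD. Pixel noise is additive Gaussian with SD 0.05 of the AIF
peak — there is no published acquisition-noise estimate for this
protocol, so this is a stated choice; Gaussian (not Rician) because at
first-pass magnitude SNR the difference is immaterial for slope fitting.

What the phantom does *not* emulate: cardiac/respiratory motion, contrast
dispersion differences between states, k-space/sequence physics, papillary
muscles, through-plane variation within a slice, RV anatomy. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the stated signal model, not robustness to real-world artefacts.

## Calibration and problem sizes

- Type-I calibration draws per-subject values from the generator's
  subject-level distribution with all groups set to the control
  configuration (1000 cohorts of 9/15/12). Rank tests are
  distribution-free under a continuous null, so rendering images would
  change nothing but the runtime; the image-level null is covered
  separately by the control-only pipeline test.
- Noisy-recovery checks use 13 HCM subjects (208 segments) through the
  full image pipeline; class-recovery checks use 10 replicates of a
  12-subject HCM cohort (~190 analyzable segments each).
- Scar recovery uses 50 single-slice phantoms with scar fractions 0–20%
  and contrasts 8–12 SD.

## Numerical notes and limitations

- Dynamic frames are stored float32 (float64 available for exactness
  tests); all fitting is float64.
- Contour radii are interpolated linearly in polar coordinates about the
  endocardial centroid, exact for star-convex contours; strongly
  non-star-convex walls are outside the geometry model.
- Sector masks are rasterized by pixel-center-in-polygon; areas on a
  64-pixel grid carry ~1–2% pixelation error, which is why voxel-oracle
  comparisons use 256²-equivalent resolution.
- The hypoperfusion rule (pixel below 0.5× the remote-median normalized
  upslope on the stress map; remote = LVH−LGE− segments of the same
  slice, falling back to the brightest sextant) is a numeric
  operationalization of what is visually delineated in clinical
  practice; there is no published numeric rule, and the measured area is
  sector-quantized in the phantom.
- All randomness flows from explicit integer seeds; identical seed and
  configuration reproduce bit-identical images and byte-identical output
  files (gzip timestamps are pinned by the NIfTI writer).
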