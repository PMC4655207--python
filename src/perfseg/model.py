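"""Model/Results layer: per-subject and cohort perfusion analysis.

:class:`SubjectPerfusionModel` wraps one subject's images and contours and
``fit()`` runs the full regional analysis — transmural contraction, AHA
segmentation, upslope fitting with AIF normalization, stress/rest reserve
ratio, scar quantification, tissue classification and area measurement —
returning a :class:`SubjectResults` with a per-segment table and summary.

:class:`CohortPerfusionModel` fits every subject and layers the group
statistics on top (Kruskal-Wallis with Dunn's post hoc across tissue
classes and groups, paired area comparisons), returning
:class:`CohortResults`.  :func:`run_pipeline` is the end-to-end entry
point used by the command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import lge as lge_mod
from . import perfusion as perf
from . import stats as st
from .cohort import LEVELS, SubjectDataset
from .geometry import ContourSet, sector_angle_bins
from .phantom import PerfusionSeries

logger = logging.getLogger("perfseg")

__all__ = [
    "AnalysisConfig",
    "SubjectPerfusionModel",
    "SubjectResults",
    "CohortPerfusionModel",
    "CohortResults",
    "run_pipeline",
]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their working defaults.

    ``window`` is the upslope fitting window in frames; ``contraction``
    the transmural contraction fraction applied endo- and epicardially;
    ``threshold_factor`` the hypoperfusion rule (pixel below this fraction
    of the remote-median normalized upslope); ``scar_c`` the LGE threshold
    in remote SD units.
    """

    window: int = 5
    contraction: float = 0.10
    threshold_factor: float = 0.5
    r_min: float = 0.8
    overlap_min: float = 0.5
    baseline_correction: bool = True
    aif_disc_fraction: float = 0.5
    scar_c: float = 5.0
    scar_min_size: int = 10
    partial_volume: bool = True
    lge_min_fraction: float = 0.05
    adult_threshold_mm: float = 13.0
    z_cutoff: float = 3.0
    slice_tolerance_mm: float = 5.0
    bsa_formula: str = "mosteller"
    aggregate: str = "mean"
    adjustment: str = "bonferroni"
    alpha: float = 0.05
    paired_area_test: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _aif_disc_mask(
    endo: geo.Contour, shape: tuple[int, int], fraction: float
) -> np.ndarray:
    """Eroded blood-pool disc: ``fraction`` of the mean endocardial radius.

    Keeps the AIF sample away from papillary-muscle and partial-volume
    pixels near the endocardial border.
    """
    c = endo.centroid
    ang = np.linspace(-np.pi, np.pi, 90, endpoint=False)
    r = fraction * float(endo.radii_at(ang, c).mean())
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r**2


def _segment_thickness(
    profile: geo.ThicknessProfile, rv_angle: float, level: str
) -> dict[int, float]:
    """Maximum wall thickness per AHA segment from an angular profile."""
    edges, ids = sector_angle_bins(level)
    n = len(ids)
    offset = edges[0]
    phi = np.mod(profile.angles - rv_angle - offset, 2.0 * np.pi)
    bins = np.minimum((phi / (2.0 * np.pi / n)).astype(int), n - 1)
    out = {}
    for j, sid in enumerate(ids):
        vals = profile.thickness[bins == j]
        vals = vals[np.isfinite(vals)]
        out[sid] = float(vals.max()) if vals.size else float("nan")
    return out


@dataclass
class SubjectResults:
    """Fitted per-subject results.

    ``segments`` has one row per (level, segment) with upslopes, AIF
    normalization, stress/rest ratio, wall thickness, LGE flag and tissue
    class; ``areas`` carries the per-subject mean hypoperfused (rest and
    stress) and fibrotic percentages of slice area.
    """

    subject_id: str
    group: str
    segments: pd.DataFrame
    lv_metrics: dict
    areas: dict
    scar: dict
    config: AnalysisConfig

    def summary(self) -> str:
        m, a, s = self.lv_metrics, self.areas, self.scar
        kept = self.segments[~self.segments["excluded"]]
        lines = [
            f"Subject {self.subject_id} ({self.group})",
            "-" * 46,
            f"EDV {m['edv_ml']:.0f} ml  ESV {m['esv_ml']:.0f} ml  "
            f"EF {m['ef_pct']:.0f}%  LVM {m['lvm_g']:.0f} g  BSA {m['bsa_m2']:.2f} m2",
            f"Max wall thickness: IVS {m['max_ivs_mm']:.1f} mm  PW {m['max_pw_mm']:.1f} mm",
            f"Hypoperfused area: rest {a['rest_pct']:.1f}%  stress {a['stress_pct']:.1f}%  "
            f"LGE {a['lge_pct']:.1f}% of slice area",
            f"Scar: {s['scar_pct_lvm']:.1f}% of LVM ({s['scar_volume_ml']:.1f} ml)",
            f"Segments analyzed: {len(kept)}/{len(self.segments)}",
        ]
        for cls, grp in kept.groupby("tissue_class", observed=True):
            lines.append(
                f"  {cls}: n={len(grp)}  upslope ratio "
                f"median {grp['upslope_ratio'].median():.2f}"
            )
        return "\n".join(lines)


class SubjectPerfusionModel:
    """Regional perfusion/LGE analysis of one subject.

    Parameters
    ----------
    dataset : SubjectDataset
        Images, contours and metadata for one subject (synthetic or
        loaded from disk).
    config : AnalysisConfig, optional
    z_table : perfseg.stats.ZTable, optional
        Normative thickness table for pediatric LVH classification; the
        packaged synthetic table is used when omitted.
    """

    def __init__(
        self,
        dataset: SubjectDataset,
        config: AnalysisConfig | None = None,
        z_table: st.ZTable | None = None,
    ) -> None:
        self.dataset = dataset
        self.config = config or AnalysisConfig()
        self.z_table = z_table or st.load_default_z_table()

    # -- helpers -----------------------------------------------------------
    def _fit_state_curve(
        self, series: PerfusionSeries, mask: np.ndarray
    ) -> perf.UpslopeFit:
        curve = perf.mean_signal_curve(series, mask)
        if self.config.baseline_correction and curve.n_baseline >= 2:
            curve = perf.baseline_correct(curve)
        return perf.max_upslope(curve, window=self.config.window)

    def fit(self) -> SubjectResults:
        ds, cfg = self.dataset, self.config
        ed = ds.cine_contours["ED"]
        es = ds.cine_contours["ES"]
        rv = ed.rv_insertion_angle

        # global LV metrics from cine planimetry
        edv, esv, sv, ef = geo.lv_volumes(ed, es)
        lvm = geo.lv_mass(ed)
        bsa = geo.bsa(ds.height, ds.weight, cfg.bsa_formula)
        # IVS/PW maxima from the basal and mid slices
        profs = [
            geo.wall_thickness_profile(
                ed.endo[z], ed.epi[z], n_rays=180,
                pixel_spacing=ed.pixel_spacing, rv_insertion_angle=rv,
            )
            for z in range(min(2, ed.n_slices))
        ]
        lv_metrics = {
            "edv_ml": edv, "esv_ml": esv, "sv_ml": sv, "ef_pct": ef,
            "lvm_g": lvm, "bsa_m2": bsa,
            "edv_i": geo.index_by_bsa(edv, bsa),
            "esv_i": geo.index_by_bsa(esv, bsa),
            "lvm_i": geo.index_by_bsa(lvm, bsa),
            "max_ivs_mm": max(p.max_ivs for p in profs),
            "max_pw_mm": max(p.max_pw for p in profs),
        }

        # co-registration between stacks
        perf_pos = ds.perfusion_contours.slice_positions
        lge_pairs = dict(
            geo.match_slices(perf_pos, ds.lge_contours.slice_positions,
                             cfg.slice_tolerance_mm)
        )
        cine_pairs = dict(
            geo.match_slices(perf_pos, ed.slice_positions, cfg.slice_tolerance_mm)
        )

        rows = []
        rest_areas, stress_areas, lge_areas = [], [], []
        scar_vol = 0.0
        for z, level in enumerate(LEVELS[: len(perf_pos)]):
            rest = ds.rest_series[level]
            stress = ds.stress_series[level]
            shape = rest.frames.shape[1:]
            endo = ds.perfusion_contours.endo[z]
            epi = ds.perfusion_contours.epi[z]
            c_endo, c_epi = geo.contract_annulus(endo, epi, cfg.contraction)
            seg = geo.aha_sector_masks(c_endo, c_epi, rv, level, shape)

            # wall thickness per segment from the matched cine slice
            zc = cine_pairs.get(z)
            if zc is not None:
                prof = geo.wall_thickness_profile(
                    ed.endo[zc], ed.epi[zc], n_rays=180,
                    pixel_spacing=ed.pixel_spacing, rv_insertion_angle=rv,
                )
                seg_thick = _segment_thickness(prof, rv, level)
            else:
                seg_thick = {sid: float("nan") for sid in seg.segment_ids}

            # LGE scar on the matched slice
            zl = lge_pairs.get(z)
            if zl is not None:
                lge_img = ds.lge_stack[LEVELS[zl]]
                myo = geo.annulus_mask(
                    ds.lge_contours.endo[zl], ds.lge_contours.epi[zl], lge_img.shape
                )
                scar_res = lge_mod.quantify_scar(
                    lge_img, myo,
                    pixel_spacing_mm=ds.lge_contours.pixel_spacing,
                    slice_thickness_mm=ds.lge_contours.slice_thickness,
                    c=cfg.scar_c, min_size=cfg.scar_min_size,
                    partial_volume=cfg.partial_volume,
                )
                scar_vol += scar_res.scar_volume_ml
                lge_flags = lge_mod.segment_lge_status(
                    scar_res.scar_mask, seg, cfg.lge_min_fraction
                )
                lge_areas.append(
                    lge_mod.lge_area_percent(scar_res.scar_mask, myo)
                )
            else:
                scar_res = None
                lge_flags = {sid: None for sid in seg.segment_ids}

            # tissue classes (needed for the remote reference region)
            classes = {}
            for sid in seg.segment_ids:
                flag = lge_flags.get(sid)
                if flag is None or not np.isfinite(seg_thick[sid]):
                    classes[sid] = None
                    continue
                classes[sid] = st.classify_segment(
                    seg_thick[sid], ds.age, flag,
                    z_table=self.z_table, bsa_m2=bsa,
                    adult_threshold_mm=cfg.adult_threshold_mm,
                    z_cutoff=cfg.z_cutoff,
                )

            # AIF per state from the eroded blood-pool disc
            aif_mask = _aif_disc_mask(endo, shape, cfg.aif_disc_fraction)
            aif_rest = self._fit_state_curve(rest, aif_mask)
            aif_stress = self._fit_state_curve(stress, aif_mask)

            remote = np.zeros(shape, dtype=bool)
            for sid in seg.segment_ids:
                if classes.get(sid) == "LVH-LGE-":
                    remote |= seg.masks[sid]
            remote_mask = remote if remote.any() else None

            for state, series_, aif_fit in (
                ("rest", rest, aif_rest), ("stress", stress, aif_stress)
            ):
                umap = perf.pixel_upslope_map(
                    series_, seg.annulus, aif_fit, window=cfg.window
                )
                area = perf.hypoperfused_area(
                    umap, seg.annulus, remote_mask, cfg.threshold_factor
                )
                (rest_areas if state == "rest" else stress_areas).append(area)

            for sid in seg.segment_ids:
                fit_rest = self._fit_state_curve(rest, seg.masks[sid])
                fit_stress = self._fit_state_curve(stress, seg.masks[sid])
                norm_rest = perf.normalized_upslope(fit_rest, aif_rest)
                norm_stress = perf.normalized_upslope(fit_stress, aif_stress)
                keep, reason = perf.exclude_mismatch(
                    fit_rest, fit_stress,
                    r_min=cfg.r_min,
                    mask_dice=perf.dice_coefficient(seg.masks[sid], seg.masks[sid]),
                    overlap_min=cfg.overlap_min,
                )
                if classes.get(sid) is None:
                    keep, reason = False, reason or "unmatched slice"
                ratio = (
                    perf.upslope_ratio(norm_stress, norm_rest)
                    if norm_rest > 0 else float("nan")
                )
                rows.append({
                    "subject_id": ds.subject_id,
                    "group": ds.group,
                    "level": level,
                    "slice_index": z,
                    "segment_id": sid,
                    "thickness_mm": seg_thick[sid],
                    "lge_flag": lge_flags.get(sid),
                    "tissue_class": classes.get(sid),
                    "upslope_rest": fit_rest.slope,
                    "upslope_stress": fit_stress.slope,
                    "aif_rest": aif_rest.slope,
                    "aif_stress": aif_stress.slope,
                    "norm_rest": norm_rest,
                    "norm_stress": norm_stress,
                    "upslope_ratio": ratio,
                    "r2_rest": fit_rest.r_squared,
                    "r2_stress": fit_stress.r_squared,
                    "excluded": not keep,
                    "exclusion_reason": reason,
                })

        segments = pd.DataFrame(rows)
        areas = {
            "rest_pct": float(np.mean(rest_areas)) if rest_areas else float("nan"),
            "stress_pct": float(np.mean(stress_areas)) if stress_areas else float("nan"),
            "lge_pct": float(np.mean(lge_areas)) if lge_areas else float("nan"),
        }
        scar = {
            "scar_volume_ml": scar_vol,
            "scar_pct_lvm": lge_mod.scar_percent_of_lvm(scar_vol, lvm),
        }
        return SubjectResults(
            subject_id=ds.subject_id, group=ds.group, segments=segments,
            lv_metrics=lv_metrics, areas=areas, scar=scar, config=cfg,
        )


@dataclass
class CohortResults:
    """Fitted cohort-level results.

    ``segments`` pools every subject's per-segment table;
    ``class_comparison`` tests the perfusion reserve across tissue classes
    (segment level), ``class_comparison_per_patient`` the per-patient
    averages; ``area_comparison`` the paired rest/stress/LGE areas in the
    HCM group.
    """

    subject_results: list[SubjectResults]
    segments: pd.DataFrame
    per_patient: pd.DataFrame
    class_comparison: st.GroupComparison | None
    class_comparison_per_patient: st.GroupComparison | None
    group_comparison: st.GroupComparison | None
    area_comparison: dict | None
    config: AnalysisConfig
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Cohort analysis: {len(self.subject_results)} subjects "
            f"({len(self.skipped)} skipped)",
            "=" * 56,
        ]
        kept = self.segments[~self.segments["excluded"]]
        lines.append(
            f"Segments analyzed: {len(kept)}/{len(self.segments)} "
            f"({len(self.segments) - len(kept)} excluded)"
        )
        for cls in st.TISSUE_CLASSES:
            sub = kept[kept["tissue_class"] == cls]
            if len(sub):
                med = sub["upslope_ratio"].median()
                lo, hi = sub["upslope_ratio"].min(), sub["upslope_ratio"].max()
                lines.append(
                    f"  {cls}: n={len(sub)}  upslope ratio {med:.2f} ({lo:.2f}-{hi:.2f})"
                )
        if self.class_comparison is not None:
            cc = self.class_comparison
            lines.append(
                f"Tissue-class Kruskal-Wallis (segments): H={cc.H:.1f}, p={cc.p:.3g}"
            )
            if cc.posthoc is not None:
                for _, r in cc.posthoc.iterrows():
                    lines.append(
                        f"  Dunn {r['group_a']} vs {r['group_b']}: "
                        f"z={r['z']:.2f}, p_adj={r['p_adj']:.3g}"
                    )
        if self.area_comparison is not None:
            ac = self.area_comparison
            lines.append(
                f"Areas (HCM, n={ac['n']}): stress vs rest p={ac['stress_vs_rest_p']:.3g}; "
                f"stress vs LGE p={ac['stress_vs_lge_p']:.3g}; "
                f"stress >= LGE in all subjects: {ac['all_stress_ge_lge']}"
            )
        return "\n".join(lines)


class CohortPerfusionModel:
    """Whole-cohort analysis: subject fits plus group statistics."""

    def __init__(
        self,
        subjects: list[SubjectDataset],
        config: AnalysisConfig | None = None,
        z_table: st.ZTable | None = None,
    ) -> None:
        self.subjects = subjects
        self.config = config or AnalysisConfig()
        self.z_table = z_table or st.load_default_z_table()

    def fit(self) -> CohortResults:
        cfg = self.config
        results: list[SubjectResults] = []
        skipped: list[tuple[str, str]] = []
        for ds in self.subjects:
            try:
                results.append(
                    SubjectPerfusionModel(ds, cfg, self.z_table).fit()
                )
            except Exception as exc:  # subject failures are isolated
                logger.warning("subject %s skipped: %s", ds.subject_id, exc)
                skipped.append((ds.subject_id, str(exc)))
        if not results:
            raise RuntimeError("no subject could be analyzed")
        segments = pd.concat([r.segments for r in results], ignore_index=True)
        per_patient = st.per_patient_aggregate(
            segments, value="upslope_ratio", how=cfg.aggregate
        )

        def _compare(values: dict[str, np.ndarray]) -> st.GroupComparison | None:
            values = {k: np.asarray(v, float) for k, v in values.items()
                      if len(v) > 0}
            if len(values) < 2:
                return None
            H, p = st.kruskal_wallis(values)
            post = st.dunn_posthoc(values, cfg.adjustment) if p < cfg.alpha else None
            return st.GroupComparison(groups=values, H=H, p=p, posthoc=post,
                                      alpha=cfg.alpha)

        kept = segments[~segments["excluded"]].dropna(subset=["upslope_ratio"])
        hcm_kept = kept[kept["group"] == "hcm"]
        class_cmp = _compare({
            cls: hcm_kept.loc[hcm_kept["tissue_class"] == cls, "upslope_ratio"].to_numpy()
            for cls in ("LVH-LGE-", "LVH+LGE-", "LVH+LGE+")
        })
        ppv = f"upslope_ratio_{cfg.aggregate}"
        subj_group = segments.groupby("subject_id")["group"].first()
        pp = per_patient.assign(group=per_patient["subject_id"].map(subj_group))
        pp_hcm = pp[pp["group"] == "hcm"]
        class_cmp_pp = _compare({
            cls: pp_hcm.loc[pp_hcm["tissue_class"] == cls, ppv].to_numpy()
            for cls in ("LVH-LGE-", "LVH+LGE-", "LVH+LGE+")
        })
        subj_means = kept.groupby("subject_id")["upslope_ratio"].mean()
        group_cmp = _compare({
            g: subj_means[subj_group[subj_means.index] == g].to_numpy()
            for g in ("control", "hcm_risk", "hcm")
        })
        areas_df = pd.DataFrame(
            [{"subject_id": r.subject_id, "group": r.group, **r.areas}
             for r in results]
        )
        hcm_areas = areas_df[areas_df["group"] == "hcm"]
        area_cmp = (
            st.area_comparison(hcm_areas, paired=cfg.paired_area_test, alpha=cfg.alpha)
            if len(hcm_areas) >= 2 else None
        )
        return CohortResults(
            subject_results=results, segments=segments, per_patient=pp,
            class_comparison=class_cmp, class_comparison_per_patient=class_cmp_pp,
            group_comparison=group_cmp, area_comparison=area_cmp,
            config=cfg, skipped=skipped,
        )


def null_typeI_rate(
    cohort_config=None,
    n_cohorts: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I calibration of the omnibus test under the null generator.

    Every group draws its per-subject perfusion-reserve values from the
    *control* configuration's subject-level sampling distribution (the
    generator's multiplicative jitter around the common stress/rest ratio,
    plus a small measurement term), i.e. all groups are identically
    distributed.  Because the Kruskal-Wallis statistic is rank-based, its
    rejection rate under a continuous null depends only on the group
    sizes, so this calibration needs no image rendering.  Returns the
    fraction of cohorts with omnibus p below ``alpha``.
    """
    from .cohort import CohortConfig

    cfg = cohort_config or CohortConfig()
    p = cfg.params
    gp = p["groups"]["control"]
    sizes = {g: int(p["n_per_group"][g]) for g in p["n_per_group"]}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        groups = {
            g: gp["stress_rest_ratio"]
            * np.exp(rng.normal(0.0, gp["subject_jitter_sd"], n))
            * np.exp(rng.normal(0.0, 0.02, n))
            for g, n in sizes.items()
        }
        _, pv = st.kruskal_wallis(groups)
        hits += pv < alpha
    return hits / n_cohorts


def replicate_class_recovery(
    cohort_config=None,
    n_subjects: int = 12,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """One HCM-cohort replicate: tissue-class recovery and area nesting.

    Generates ``n_subjects`` HCM subjects with the default generator,
    runs the full image pipeline, and reports the per-class medians, the
    median ordering flag (LVH+LGE+ < LVH+LGE- < LVH-LGE-), the two Dunn
    contrast p-values (unadjusted; see docs/methods.md for why the
    Bonferroni-adjusted contrast between the two small classes is
    power-limited by the large reference class), and the per-subject
    stress-area >= LGE-area flags.
    """
    from .cohort import CohortConfig, generate_subject

    cfg = cohort_config or CohortConfig()
    rng = np.random.default_rng(seed)
    subjects = [
        generate_subject("hcm", cfg, int(rng.integers(2**31)),
                         subject_id=f"hcm_{i:02d}")
        for i in range(n_subjects)
    ]
    acfg = AnalysisConfig(adjustment="none", alpha=alpha)
    res = CohortPerfusionModel(subjects, acfg).fit()
    cc = res.class_comparison
    medians = {
        cls: float(np.median(cc.groups[cls])) for cls in cc.groups
    } if cc else {}
    ordered = (
        len(medians) == 3
        and medians["LVH+LGE+"] < medians["LVH+LGE-"] < medians["LVH-LGE-"]
    )
    dunn_p: dict[str, float] = {}
    if cc is not None and cc.posthoc is not None:
        for _, r in cc.posthoc.iterrows():
            dunn_p[f"{r['group_a']} vs {r['group_b']}"] = float(r["p"])
    ac = res.area_comparison
    flags = ac["stress_ge_lge_flags"] if ac else {}
    truth_nested = {
        s.subject_id: all(
            (s.ground_truth.scar_mask[lvl] <= s.ground_truth.hypoperfused_mask[lvl]).all()
            for lvl in s.ground_truth.scar_mask
        )
        for s in subjects
    }
    return {
        "medians": medians,
        "ordering_recovered": bool(ordered),
        "dunn_p": dunn_p,
        "stress_ge_lge_flags": flags,
        "truth_nested": truth_nested,
        "omnibus_p": float(cc.p) if cc else float("nan"),
    }


def run_pipeline(
    source,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> CohortResults:
    """End-to-end cohort run.

    ``source`` is either a list of :class:`SubjectDataset` or a directory
    containing a simulated cohort (``manifest.csv``).  When ``out_dir`` is
    given, writes ``segments.csv``, ``subjects.json`` and
    ``cohort_stats.csv`` plus a run log with the config hash.
    """
    from .io import load_cohort

    cfg = config or AnalysisConfig()
    if isinstance(source, (str, Path)):
        subjects = load_cohort(source)
    else:
        subjects = list(source)
    res = CohortPerfusionModel(subjects, cfg).fit()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        res.segments.round(6).to_csv(out / "segments.csv", index=False)
        subj_payload = {
            r.subject_id: {
                "group": r.group,
                "lv_metrics": {k: round(float(v), 4) for k, v in r.lv_metrics.items()},
                "areas": {k: round(float(v), 4) for k, v in r.areas.items()},
                "scar": {k: round(float(v), 4) for k, v in r.scar.items()},
            }
            for r in res.subject_results
        }
        (out / "subjects.json").write_text(json.dumps(subj_payload, sort_keys=True,
                                                      indent=1))
        stats_rows = []
        for name, cmp_ in (
            ("tissue_class_segments", res.class_comparison),
            ("tissue_class_per_patient", res.class_comparison_per_patient),
            ("groups_subject_means", res.group_comparison),
        ):
            if cmp_ is None:
                continue
            stats_rows.append({"comparison": name, "pair": "omnibus",
                               "stat": cmp_.H, "p": cmp_.p})
            if cmp_.posthoc is not None:
                for _, r in cmp_.posthoc.iterrows():
                    stats_rows.append({
                        "comparison": name,
                        "pair": f"{r['group_a']} vs {r['group_b']}",
                        "stat": r["z"], "p": r["p_adj"],
                    })
        if res.area_comparison is not None:
            ac = res.area_comparison
            stats_rows.append({"comparison": "area_stress_vs_rest", "pair": "paired",
                               "stat": float("nan"), "p": ac["stress_vs_rest_p"]})
            stats_rows.append({"comparison": "area_stress_vs_lge", "pair": "paired",
                               "stat": float("nan"), "p": ac["stress_vs_lge_p"]})
        pd.DataFrame(stats_rows).round(8).to_csv(out / "cohort_stats.csv", index=False)
        n_excl = int(res.segments["excluded"].sum())
        (out / "run_log.json").write_text(json.dumps({
            "config_hash": cfg.config_hash(),
            "n_subjects": len(res.subject_results),
            "n_skipped": len(res.skipped),
            "n_segments": int(len(res.segments)),
            "n_excluded_segments": n_excl,
        }, sort_keys=True, indent=1))
    return res
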