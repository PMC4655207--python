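"""Synthetic subject and cohort generation.

Builds seeded phantom subjects in three groups — healthy controls,
HCM-risk (mutation carriers / first-degree relatives without hypertrophy)
and HCM patients — whose images carry the statistical and geometric
structure the downstream analysis assumes, together with full ground truth
for parameter-recovery testing.

Group-level defaults live in one editable YAML block
(``perfseg/data/default_cohort.yaml``) so cohort-level experiments are
configuration, not code.  The default stress/rest transfer-factor ratios
(2.1 control, 2.2 risk; 2.0 / 1.5 / 0.9 for normal, hypertrophied and
scarred HCM sectors) and group sizes (9 / 15 / 12) are calibrated to the
cohort the analysis is designed around.  HCM subjects have hypertrophied
septal sectors with reduced stress perfusion and a scar wedge nested
inside a subset of those sectors, so scar ⊆ hypoperfusion ⊆ hypertrophy
holds by construction; controls and risk subjects have uniform perfusion
and no scar.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import AHA_BIN_IDS, Contour, ContourSet, Level, sector_angle_bins
from .kinetics import KineticParams, generate_aif_curve
from .phantom import (
    PerfusionSeries,
    PhantomGeometry,
    generate_lge_image,
    make_annulus_contours,
    render_phantom_slice,
    scar_wedge_mask,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SubjectDataset",
    "LEVELS",
    "default_config",
    "generate_subject",
    "generate_cohort",
]

LEVELS: tuple[Level, ...] = ("basal", "mid", "apical")
GROUPS = ("control", "hcm_risk", "hcm")


def default_config() -> dict:
    """The editable cohort configuration block, loaded from package data."""
    text = resources.files("perfseg.data").joinpath("default_cohort.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class CohortConfig:
    """Validated cohort configuration.

    Constructed from the default YAML block with optional overrides;
    identical ``seed`` and parameters yield a bit-identical cohort.
    """

    params: dict = field(default_factory=default_config)
    seed: int = 42

    def __post_init__(self) -> None:
        p = self.params
        for g in GROUPS:
            if g not in p["groups"]:
                raise ValueError(f"missing group {g!r} in config")
            if p["n_per_group"][g] < 1:
                raise ValueError("group sizes must be >= 1")
        if p["noise_sd_fraction"] < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if p["timing"]["n_frames"] < 4 or p["timing"]["frame_interval_s"] <= 0:
            raise ValueError("invalid frame timing")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "CohortConfig":
        params = yaml.safe_load(Path(path).read_text())
        base = default_config()
        _deep_update(base, params or {})
        return cls(params=base, seed=base["seed"] if seed is None else seed)

    def with_overrides(self, **updates) -> "CohortConfig":
        params = copy.deepcopy(self.params)
        _deep_update(params, updates)
        return CohortConfig(params=params, seed=self.seed)


def _deep_update(base: dict, updates: dict) -> None:
    for k, v in updates.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


@dataclass
class GroundTruth:
    """Per-subject ground truth for recovery testing.

    ``perfusion_factors[level][segment_id] = (k_rest, k_stress)`` are the
    sector transfer factors; masks are per-level 2-D boolean maps.  In the
    default configuration scar ⊆ hypoperfused ⊆ hypertrophied sectors.
    """

    perfusion_factors: dict[str, dict[int, tuple[float, float]]]
    scar_mask: dict[str, np.ndarray]
    hypoperfused_mask: dict[str, np.ndarray]
    thickness_profile_mm: dict[str, np.ndarray]
    lvh_segments: list[tuple[str, int]]
    scar_segments: list[tuple[str, int]]


@dataclass
class SubjectDataset:
    """One synthetic subject: images, contours, metadata and ground truth."""

    subject_id: str
    group: str
    age: float
    height: float
    weight: float
    rest_series: dict[str, PerfusionSeries]
    stress_series: dict[str, PerfusionSeries]
    lge_stack: dict[str, np.ndarray]
    cine_contours: dict[str, ContourSet]  # phases "ED" and "ES"
    perfusion_contours: ContourSet
    lge_contours: ContourSet
    ground_truth: GroundTruth
    seed: int = 0


def _plateau_bump(phi: np.ndarray, span: tuple[float, float], ramp: float = 0.15) -> np.ndarray:
    """Membership in an angular span with cosine-ramped edges.

    ``phi`` and the span are in radians relative to the RV insertion; the
    bump is 1 on the central plateau and ramps to 0 over the outer
    ``ramp`` fraction of the span on each side.
    """
    lo, hi = span
    width = hi - lo
    u = np.mod(phi - lo, 2.0 * np.pi) / width  # in [0, 1) inside the span
    out = np.zeros_like(phi)
    inside = u < 1.0
    uu = u[inside]
    w = np.ones_like(uu)
    left = uu < ramp
    right = uu > 1.0 - ramp
    w[left] = 0.5 - 0.5 * np.cos(np.pi * uu[left] / ramp)
    w[right] = 0.5 - 0.5 * np.cos(np.pi * (1.0 - uu[right]) / ramp)
    out[inside] = w
    return out


def _segment_spans(level: Level) -> dict[int, tuple[float, float]]:
    edges, ids = sector_angle_bins(level)
    width = 2.0 * np.pi / len(ids)
    return {sid: (float(e), float(e + width)) for e, sid in zip(edges, ids)}


def _thickness_profile_mm(
    level: Level, gp: dict, config: dict, n_points: int
) -> np.ndarray:
    """Wall thickness (mm) at the phantom contour angles for one level."""
    ang = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    rv = np.deg2rad(config["image"]["rv_insertion_deg"])
    phi = np.mod(ang - rv, 2.0 * np.pi)
    free = float(gp["free_wall_thickness_mm"])
    septal = float(gp["septal_thickness_mm"])
    thick = np.full(n_points, free)
    spans = _segment_spans(level)
    for sid in gp["septal_segments"]:
        if sid in spans:
            thick += (septal - free) * _plateau_bump(phi, spans[sid])
    return thick


def _es_contours(
    ed_endo: Contour, ed_epi: Contour, ef_pct: float
) -> tuple[Contour, Contour]:
    """End-systolic contours with the prescribed area-based ejection fraction.

    Endocardial radii shrink by sqrt(1 - EF/100); epicardial radii follow so
    that the myocardial area (hence mass) is preserved per ray.
    """
    c = ed_epi.centroid
    ang = np.linspace(-np.pi, np.pi, len(ed_endo.vertices), endpoint=False)
    r_en = ed_endo.radii_at(ang, c)
    r_ep = ed_epi.radii_at(ang, c)
    scale = np.sqrt(max(1.0 - ef_pct / 100.0, 1e-3))
    r_en_es = r_en * scale
    r_ep_es = np.sqrt(r_en_es**2 + r_ep**2 - r_en**2)

    def _poly(r: np.ndarray) -> np.ndarray:
        return np.column_stack([c[0] + r * np.cos(ang), c[1] - r * np.sin(ang)])

    mk = lambda r: Contour(_poly(r), ed_endo.slice_index, ed_endo.slice_position)
    return mk(r_en_es), mk(r_ep_es)


def generate_subject(
    group: str, config: CohortConfig, seed: int, subject_id: str | None = None
) -> SubjectDataset:
    """Generate one seeded synthetic subject of the given group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    p = config.params
    gp = p["groups"][group]
    img, timing = p["image"], p["timing"]
    rng = np.random.default_rng(seed)
    subject_id = subject_id or f"{group}_{seed:010d}"

    age = float(rng.uniform(*gp["age_range"]))
    height = float(np.clip(rng.normal(172.0, 9.0) - (8.0 if age < 16 else 0.0), 145, 200))
    weight = float(np.clip(rng.normal(68.0, 11.0) - (10.0 if age < 16 else 0.0), 38, 105))
    ef = float(np.clip(rng.normal(gp["ejection_fraction"], 3.0), 30.0, 75.0))
    subj_jitter = float(np.exp(rng.normal(0.0, gp["subject_jitter_sd"])))

    frame_times = timing["frame_interval_s"] * np.arange(timing["n_frames"])
    aif_params = KineticParams(
        amplitude=p["aif"]["amplitude"],
        alpha=p["aif"]["alpha"],
        beta=p["aif"]["beta"],
        t0=timing["bolus_arrival_s"],
    )
    aif = generate_aif_curve(aif_params, frame_times, baseline=p["aif"]["baseline"])
    noise_sd = p["noise_sd_fraction"] * p["aif"]["amplitude"]

    lvh_segments = [(lvl, sid) for lvl in LEVELS for sid in gp["lvh_segments"]
                    if sid in AHA_BIN_IDS[lvl]]
    n_scar = int(gp.get("n_scar_segments", 0))
    scar_segments: list[tuple[str, int]] = []
    if n_scar > 0 and lvh_segments:
        idx = rng.choice(len(lvh_segments), size=min(n_scar, len(lvh_segments)),
                         replace=False)
        scar_segments = [lvh_segments[i] for i in sorted(idx)]

    rv_angle = np.deg2rad(img["rv_insertion_deg"])
    rest_series: dict[str, PerfusionSeries] = {}
    stress_series: dict[str, PerfusionSeries] = {}
    lge_stack: dict[str, np.ndarray] = {}
    ed_endo: list[Contour] = []
    ed_epi: list[Contour] = []
    es_endo: list[Contour] = []
    es_epi: list[Contour] = []
    factors: dict[str, dict[int, tuple[float, float]]] = {}
    scar_masks: dict[str, np.ndarray] = {}
    hypo_masks: dict[str, np.ndarray] = {}
    thick_profiles: dict[str, np.ndarray] = {}

    for z, level in enumerate(LEVELS):
        lvlp = p["levels"][level]
        thick_mm = _thickness_profile_mm(level, gp, p, img["n_contour_points"])
        geom = PhantomGeometry(
            shape=tuple(img["shape"]),
            endo_radius_px=lvlp["endo_radius_px"],
            wall_thickness_px=thick_mm / img["pixel_spacing_mm"],
            pixel_spacing_mm=img["pixel_spacing_mm"],
            slice_thickness_mm=img["slice_thickness_mm"],
            n_contour_points=img["n_contour_points"],
            rv_insertion_angle=rv_angle,
            slice_index=z,
            slice_position_mm=lvlp["slice_position_mm"],
        )
        thick_profiles[level] = thick_mm

        k_rest_base = float(p["tissue"]["k_rest"])
        lvl_factors: dict[int, tuple[float, float]] = {}
        for sid in AHA_BIN_IDS[level]:
            if (level, sid) in scar_segments:
                ratio = gp.get("scar_stress_rest_ratio", gp["stress_rest_ratio"])
            elif (level, sid) in lvh_segments:
                ratio = gp.get("lvh_stress_rest_ratio", gp["stress_rest_ratio"])
            else:
                ratio = gp["stress_rest_ratio"]
            sector_jitter = float(np.exp(rng.normal(0.0, gp.get("sector_jitter_sd", 0.03))))
            k_rest = k_rest_base
            k_stress = float(np.clip(k_rest * ratio * subj_jitter * sector_jitter,
                                     1e-3, 1.5))
            lvl_factors[sid] = (k_rest, k_stress)
        factors[level] = lvl_factors

        for state, series_store in (("rest", rest_series), ("stress", stress_series)):
            k_map = {sid: kk[0 if state == "rest" else 1]
                     for sid, kk in lvl_factors.items()}
            series, endo, epi, seg = render_phantom_slice(
                geom, aif, k_map,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                level=level, state=state,
                delay_s=p["tissue"]["delay_s"],
                smoothing_width=p["tissue"]["smoothing_width"],
                tissue_baseline=p["tissue"]["baseline"],
            )
            series_store[level] = series

        scar = np.zeros(tuple(img["shape"]), dtype=bool)
        hypo = np.zeros(tuple(img["shape"]), dtype=bool)
        for lvl, sid in scar_segments:
            if lvl != level:
                continue
            scar |= scar_wedge_mask(
                geom, seg, sid,
                angular_fraction=gp.get("scar_angular_fraction", 0.6),
                transmural=tuple(gp.get("scar_transmural", (0.3, 0.7))),
            )
            hypo |= seg.masks[sid]
        scar_masks[level] = scar
        hypo_masks[level] = hypo

        lge_stack[level] = generate_lge_image(
            geom, scar,
            remote_mean=p["lge"]["remote_mean"],
            remote_sd=p["lge"]["remote_sd"],
            scar_mean=p["lge"]["remote_mean"]
            + p["lge"]["scar_contrast_sd"] * p["lge"]["remote_sd"],
            seed=int(rng.integers(2**31)),
            blood_mean=p["lge"]["blood_mean"],
        )

        ed_endo.append(endo)
        ed_epi.append(epi)
        es_en, es_ep = _es_contours(endo, epi, ef)
        es_endo.append(es_en)
        es_epi.append(es_ep)

    mk_set = lambda en, ep, phase, thick: ContourSet(
        endo=en, epi=ep, rv_insertion_angle=rv_angle,
        pixel_spacing=img["pixel_spacing_mm"], slice_thickness=thick, phase=phase,
    )
    cine = {
        "ED": mk_set(ed_endo, ed_epi, "ED", img["slice_thickness_mm"]),
        "ES": mk_set(es_endo, es_epi, "ES", img["slice_thickness_mm"]),
    }
    truth = GroundTruth(
        perfusion_factors=factors,
        scar_mask=scar_masks,
        hypoperfused_mask=hypo_masks,
        thickness_profile_mm=thick_profiles,
        lvh_segments=lvh_segments,
        scar_segments=scar_segments,
    )
    return SubjectDataset(
        subject_id=subject_id, group=group, age=age, height=height, weight=weight,
        rest_series=rest_series, stress_series=stress_series, lge_stack=lge_stack,
        cine_contours=cine,
        perfusion_contours=mk_set(ed_endo, ed_epi, "perfusion",
                                  img["slice_thickness_mm"]),
        lge_contours=mk_set(ed_endo, ed_epi, "LGE", img["lge_slice_thickness_mm"]),
        ground_truth=truth, seed=seed,
    )


def generate_cohort(config: CohortConfig) -> list[SubjectDataset]:
    """Generate the full seeded cohort (control, HCM-risk, HCM)."""
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectDataset] = []
    for group in GROUPS:
        n = config.params["n_per_group"][group]
        for i in range(n):
            seed = int(rng.integers(2**31))
            subjects.append(
                generate_subject(group, config, seed, subject_id=f"{group}_{i:02d}")
            )
    return subjects
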