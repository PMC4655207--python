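"""Tissue classification and nonparametric group statistics.

Segments are cross-classified by hypertrophy (LVH+/-) and fibrosis
(LGE+/-): LVH+ means end-diastolic wall thickness above 13 mm in adults
(over 18 years) or a thickness z-score above 3 against a BSA-indexed
normative lookup in pediatric subjects.  Group and class comparisons use
the Kruskal-Wallis rank test with Dunn's post hoc test (tie-corrected,
Bonferroni-adjusted by default); paired within-subject area comparisons
use the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TISSUE_CLASSES",
    "ZTable",
    "GroupComparison",
    "load_default_z_table",
    "classify_segment",
    "kruskal_wallis",
    "dunn_posthoc",
    "per_patient_aggregate",
    "area_comparison",
]

TISSUE_CLASSES = ("LVH-LGE-", "LVH+LGE-", "LVH+LGE+", "LVH-LGE+")

ADULT_LVH_THICKNESS_MM = 13.0
PEDIATRIC_Z_CUTOFF = 3.0
ADULT_AGE_YEARS = 18.0


@dataclass
class ZTable:
    """BSA-indexed normative wall-thickness lookup (mean/SD by BSA)."""

    bsa_m2: np.ndarray
    mean_mm: np.ndarray
    sd_mm: np.ndarray

    def z(self, thickness_mm: float, bsa_m2: float) -> float:
        mu = float(np.interp(bsa_m2, self.bsa_m2, self.mean_mm))
        sd = float(np.interp(bsa_m2, self.bsa_m2, self.sd_mm))
        return (thickness_mm - mu) / sd

    @classmethod
    def from_csv(cls, path: str | Path) -> "ZTable":
        df = pd.read_csv(path, comment="#")
        df = df.sort_values("bsa_m2")
        return cls(
            bsa_m2=df["bsa_m2"].to_numpy(float),
            mean_mm=df["mean_thickness_mm"].to_numpy(float),
            sd_mm=df["sd_thickness_mm"].to_numpy(float),
        )


def load_default_z_table() -> ZTable:
    """The synthetic normative thickness table shipped with the package.

    A constructed stand-in for a published pediatric normative dataset;
    swap in a real reference via :meth:`ZTable.from_csv` for clinical use.
    """
    with resources.as_file(
        resources.files("perfseg.data").joinpath("synthetic_pediatric_thickness_norms.csv")
    ) as p:
        return ZTable.from_csv(p)


def classify_segment(
    thickness_mm: float,
    age_years: float,
    lge_flag: bool,
    z_table: ZTable | None = None,
    bsa_m2: float | None = None,
    adult_threshold_mm: float = ADULT_LVH_THICKNESS_MM,
    z_cutoff: float = PEDIATRIC_Z_CUTOFF,
) -> str:
    """Cross-classify one segment into LVH+/- x LGE+/-.

    Adults (> 18 y): LVH+ when thickness exceeds ``adult_threshold_mm``
    (13 mm).  Pediatric subjects: LVH+ when the thickness z-score against
    the BSA-indexed normative table exceeds ``z_cutoff`` (3 SD); a z-table
    and BSA are then required.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be >= 0")
    if age_years > ADULT_AGE_YEARS:
        lvh = thickness_mm > adult_threshold_mm
    else:
        if z_table is None or bsa_m2 is None:
            raise ValueError("pediatric classification requires a z-table and BSA")
        lvh = z_table.z(thickness_mm, bsa_m2) > z_cutoff
    return f"LVH{'+' if lvh else '-'}LGE{'+' if lge_flag else '-'}"


@dataclass
class GroupComparison:
    """Omnibus Kruskal-Wallis result with optional Dunn pairwise table."""

    groups: dict[str, np.ndarray]
    H: float
    p: float
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05


def kruskal_wallis(groups: dict[str, "np.ndarray | list"]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    At least two nonempty groups are required.  When every observation is
    identical the test is vacuous and ``(0.0, 1.0)`` is returned.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def dunn_posthoc(
    groups: dict[str, "np.ndarray | list"],
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise post hoc test on pooled ranks.

    For each pair the z statistic is the difference of mean ranks divided
    by its standard error under the null, with the usual tie correction
    ``sum(t^3 - t)`` on the pooled sample; two-sided p-values are
    Bonferroni-adjusted over the k(k-1)/2 pairs by default
    (``adjustment="none"`` disables).  With two groups ``z**2`` equals the
    Kruskal-Wallis H up to the tie convention.
    """
    if adjustment not in ("none", "bonferroni"):
        raise ValueError("adjustment must be 'none' or 'bonferroni'")
    names = list(groups)
    arrays = {g: np.asarray(groups[g], float) for g in names}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("empty group")
    pooled = np.concatenate([arrays[g] for g in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in names:
        m = arrays[g].size
        mean_rank[g] = float(ranks[i : i + m].mean())
        i += m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        na, nb = arrays[a].size, arrays[b].size
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (1.0 / na + 1.0 / nb)
        )
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * n_pairs) if adjustment == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def per_patient_aggregate(
    segment_table: pd.DataFrame,
    value: str = "upslope_ratio",
    how: str = "mean",
) -> pd.DataFrame:
    """Per-patient perfusion value per tissue class.

    Averages all non-excluded classified segments of one subject that share
    the same tissue class (``how`` is ``"mean"`` by default, ``"median"``
    optional); classes with zero segments are simply absent.
    """
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    df = segment_table
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=[value, "tissue_class"])
    grouped = df.groupby(["subject_id", "tissue_class"], observed=True)[value]
    agg = grouped.mean() if how == "mean" else grouped.median()
    return agg.reset_index().rename(columns={value: f"{value}_{how}"})


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; 1.0 when every pair ties."""
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)


def area_comparison(
    areas: pd.DataFrame,
    paired: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Compare per-subject hypoperfused and fibrotic area percentages.

    ``areas`` needs columns ``subject_id``, ``rest_pct``, ``stress_pct``
    and ``lge_pct``; subjects missing any modality are dropped (logged in
    the result).  Stress vs rest and stress vs LGE are paired within
    subject, so the default is the Wilcoxon signed-rank test; the unpaired
    Kruskal-Wallis alternative is kept behind ``paired=False`` for strict
    replication of rank-sum-only workflows.  Also reports the per-subject
    flag ``stress_pct >= lge_pct`` (ties count as satisfied).
    """
    req = ["subject_id", "rest_pct", "stress_pct", "lge_pct"]
    df = areas[req].copy()
    dropped = df[df[req[1:]].isna().any(axis=1)]["subject_id"].tolist()
    df = df.dropna()
    if df.empty:
        raise ValueError("no subject has all three area measurements")
    rest = df["rest_pct"].to_numpy()
    stress = df["stress_pct"].to_numpy()
    lge = df["lge_pct"].to_numpy()
    if paired:
        p_sr = _paired_wilcoxon(stress, rest)
        p_sl = _paired_wilcoxon(stress, lge)
        test = "wilcoxon_signed_rank"
    else:
        _, p_sr = kruskal_wallis({"stress": stress, "rest": rest})
        _, p_sl = kruskal_wallis({"stress": stress, "lge": lge})
        test = "kruskal_wallis"
    return {
        "test": test,
        "n": int(df.shape[0]),
        "stress_vs_rest_p": p_sr,
        "stress_vs_lge_p": p_sl,
        "stress_ge_lge_flags": dict(zip(df["subject_id"], stress >= lge)),
        "all_stress_ge_lge": bool(np.all(stress >= lge)),
        "dropped_subjects": dropped,
        "alpha": alpha,
    }
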