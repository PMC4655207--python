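"""Semiquantitative first-pass perfusion analysis.

The perfusion index implemented here is the *maximum upslope ratio*: within
each myocardial region the steepest ordinary-least-squares slope of the
signal-time curve during the first pass is normalized by the corresponding
arterial-input-function (AIF) upslope from the LV blood pool, and the
stress/rest ratio of these normalized upslopes is the myocardial perfusion
reserve index (MPRI).  No absolute quantification (deconvolution, ml/g/min)
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PerfusionSeries

__all__ = [
    "TimeCurve",
    "UpslopeFit",
    "SegmentPerfusion",
    "DegenerateAIFError",
    "mean_signal_curve",
    "baseline_correct",
    "max_upslope",
    "normalized_upslope",
    "upslope_ratio",
    "pixel_upslope_map",
    "hypoperfused_area",
    "exclude_mismatch",
    "dice_coefficient",
]


class DegenerateAIFError(ValueError):
    """Raised when the arterial input function has a non-positive upslope."""


@dataclass
class TimeCurve:
    """A sampled signal-time curve.

    ``n_baseline`` counts the pre-contrast frames used for baseline
    estimation; it must leave at least one post-baseline sample.
    """

    times: np.ndarray
    values: np.ndarray
    n_baseline: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.n_baseline < self.times.size:
            raise ValueError("n_baseline must be < curve length")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class UpslopeFit:
    """Result of the maximum-upslope linear fit.

    ``slope`` is in signal units per second; the fitted window spans frames
    ``[window_start, window_end)``.
    """

    slope: float
    window_start: int
    window_end: int
    r_squared: float


@dataclass
class SegmentPerfusion:
    """Per-segment perfusion summary across rest and stress states."""

    segment_id: int
    upslope_rest: float = np.nan
    upslope_stress: float = np.nan
    aif_rest: float = np.nan
    aif_stress: float = np.nan
    norm_rest: float = np.nan
    norm_stress: float = np.nan
    upslope_ratio: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""


def mean_signal_curve(series: "PerfusionSeries", mask: np.ndarray) -> TimeCurve:
    """Per-frame arithmetic mean of the masked pixels of a dynamic series."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.frames.shape[1:]:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("empty mask")
    vals = series.frames[:, mask].mean(axis=1)
    return TimeCurve(series.times, vals, n_baseline=series.n_baseline)


def baseline_correct(curve: TimeCurve) -> TimeCurve:
    """Subtract the mean of the pre-contrast baseline frames.

    An additive shift: every slope (hence every upslope fit) is unchanged.
    """
    if curve.n_baseline < 2:
        raise ValueError("baseline correction needs >= 2 baseline frames")
    base = curve.values[: curve.n_baseline].mean()
    return TimeCurve(curve.times, curve.values - base, curve.n_baseline)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of y on t.  R^2 is 1.0 for an exact (flat) fit."""
    tm = t - t.mean()
    ym = y - y.mean()
    stt = float(tm @ tm)
    sty = float(tm @ ym)
    syy = float(ym @ ym)
    slope = sty / stt
    if syy <= 0.0:
        return slope, 1.0
    resid = syy - sty * sty / stt
    return slope, max(0.0, 1.0 - resid / syy)


def first_pass_end(values: np.ndarray, margin: int = 2) -> int:
    """Last frame index (inclusive) of the first-pass search interval.

    The window search stops ``margin`` frames after the global peak so that
    recirculation upslopes are never selected.
    """
    return min(int(np.argmax(values)) + margin, values.size - 1)


def max_upslope(curve: TimeCurve, window: int = 5) -> UpslopeFit:
    """Maximum OLS slope over all contiguous windows of the given width.

    Every window of ``window`` consecutive frames whose last frame lies
    within the first-pass interval (up to the global peak plus two frames)
    is fitted by ordinary least squares; the window with the largest slope
    wins, ties broken by the earliest window.
    """
    if window < 2:
        raise ValueError("window must span >= 2 frames")
    n = len(curve)
    if n < window:
        raise ValueError("curve shorter than the fitting window")
    last = first_pass_end(curve.values)
    n_windows = max(1, min(n - window, last - window + 1) + 1)
    best: UpslopeFit | None = None
    for s in range(n_windows):
        sl, r2 = _ols_slope(curve.times[s : s + window], curve.values[s : s + window])
        if best is None or sl > best.slope:
            best = UpslopeFit(sl, s, s + window, r2)
    assert best is not None
    return best


def normalized_upslope(tissue: UpslopeFit, aif: UpslopeFit) -> float:
    """Tissue upslope normalized by the arterial input function upslope."""
    if aif.slope <= 0:
        raise DegenerateAIFError("non-positive AIF upslope (failed bolus?)")
    return tissue.slope / aif.slope


def upslope_ratio(norm_stress: float, norm_rest: float) -> float:
    """Stress/rest ratio of normalized upslopes (MPRI)."""
    if norm_rest <= 0:
        raise ValueError("non-positive rest normalized upslope")
    return norm_stress / norm_rest


def _sliding_slopes(frames: np.ndarray, times: np.ndarray, window: int) -> np.ndarray:
    """OLS slopes of every length-``window`` time window, vectorized.

    ``frames`` is (t, ...); returns (n_windows, ...).  The slope over a
    window is a linear functional of the in-window samples with weights
    proportional to the centered times, so each window reduces to one
    tensordot.
    """
    n = times.size
    n_windows = n - window + 1
    out = np.empty((n_windows,) + frames.shape[1:], dtype=float)
    for s in range(n_windows):
        t = times[s : s + window]
        tm = t - t.mean()
        out[s] = np.tensordot(tm, frames[s : s + window], axes=(0, 0)) / (tm @ tm)
    return out


def pixel_upslope_map(
    series: "PerfusionSeries",
    annulus_mask: np.ndarray,
    aif_fit: UpslopeFit,
    window: int = 5,
) -> np.ndarray:
    """Per-pixel maximum upslope normalized by the AIF upslope.

    Returns a float map that is NaN outside ``annulus_mask``.  Matches
    :func:`max_upslope` applied pixel by pixel (same first-pass interval
    rule and earliest-window tie-break).
    """
    if aif_fit.slope <= 0:
        raise DegenerateAIFError("non-positive AIF upslope")
    mask = np.asarray(annulus_mask, dtype=bool)
    pix = series.frames[:, mask]  # (t, n_pix)
    slopes = _sliding_slopes(pix, series.times, window)  # (n_windows, n_pix)
    last = np.minimum(np.argmax(pix, axis=0) + 2, len(series.times) - 1)
    max_start = np.minimum(last - window + 1, slopes.shape[0] - 1)
    max_start = np.maximum(max_start, 0)
    allowed = np.arange(slopes.shape[0])[:, None] <= max_start[None, :]
    best = np.where(allowed, slopes, -np.inf).max(axis=0)
    out = np.full(mask.shape, np.nan)
    out[mask] = best / aif_fit.slope
    return out


def hypoperfused_area(
    upslope_map: np.ndarray,
    annulus_mask: np.ndarray,
    remote_mask: np.ndarray | None = None,
    threshold_factor: float = 0.5,
) -> float:
    """Hypoperfused area as percent of the slice myocardial area.

    A pixel is hypoperfused when its normalized upslope falls below
    ``threshold_factor`` times the median of the remote (normal-appearing
    reference) region.  When no remote mask is supplied the fallback
    reference is the 60-deg-equivalent sextant of the annulus with the
    highest median upslope, approximated as the top sixth of pixel values.
    """
    mask = np.asarray(annulus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty annulus mask")
    vals = upslope_map[mask]
    if remote_mask is not None:
        remote_vals = upslope_map[np.asarray(remote_mask, bool) & mask]
    else:
        k = max(1, mask.sum() // 6)
        remote_vals = np.sort(vals[np.isfinite(vals)])[-k:]
    remote_vals = remote_vals[np.isfinite(remote_vals)]
    if remote_vals.size == 0:
        raise ValueError("empty remote reference region")
    thr = threshold_factor * float(np.median(remote_vals))
    hypo = np.count_nonzero(vals < thr)
    return 100.0 * hypo / mask.sum()


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def exclude_mismatch(
    rest_fit: UpslopeFit,
    stress_fit: UpslopeFit,
    r_min: float = 0.8,
    mask_dice: float | None = None,
    overlap_min: float = 0.5,
) -> tuple[bool, str]:
    """Quality gate for a segment's rest/stress fit pair.

    Returns ``(keep, reason)``.  A segment is dropped when the linear fit is
    poor (R^2 below ``r_min`` in either state, indicating artefacts) or when
    the rest/stress segment masks disagree spatially (Dice below
    ``overlap_min`` after slice matching — a "large mismatch" between
    states).
    """
    if rest_fit.r_squared < r_min:
        return False, f"rest fit r2 {rest_fit.r_squared:.2f} < {r_min}"
    if stress_fit.r_squared < r_min:
        return False, f"stress fit r2 {stress_fit.r_squared:.2f} < {r_min}"
    if mask_dice is not None and mask_dice < overlap_min:
        return False, f"rest/stress mask Dice {mask_dice:.2f} < {overlap_min}"
    return True, ""
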