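"""Contrast-kinetic curve models for the synthetic phantom.

First-pass enhancement of the LV blood pool is modelled with a
gamma-variate bolus, the standard empirical description of a first-pass
indicator-dilution curve.  Myocardial tissue enhancement is a scaled,
delayed and boxcar-smoothed copy of the arterial input function (AIF)
rather than a residue-function convolution: the downstream analysis is
semiquantitative (maximum upslope only), and this construction makes the
ground truth analytic — with unit smoothing width and an integer-frame
delay, ``max_upslope(tissue) = k * max_upslope(AIF)`` holds exactly, where
``k`` is the prescribed transfer factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perfusion import TimeCurve

__all__ = [
    "KineticParams",
    "gamma_variate",
    "generate_aif_curve",
    "generate_tissue_curve",
]


@dataclass(frozen=True)
class KineticParams:
    """Gamma-variate bolus parameters.

    Parameters
    ----------
    amplitude : float
        Peak enhancement above baseline, in signal units.  The curve is
        normalized so its maximum equals ``amplitude`` exactly.
    alpha : float
        Dimensionless shape parameter; larger values sharpen the bolus.
    beta : float
        Time constant in seconds; together with ``alpha`` it sets the
        time-to-peak ``alpha * beta`` after arrival.
    t0 : float
        Bolus arrival time in seconds.
    """

    amplitude: float = 1.0
    alpha: float = 3.0
    beta: float = 2.0
    t0: float = 10.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.alpha <= 0 or self.beta <= 0 or self.t0 < 0:
            raise ValueError(
                "gamma-variate parameters require amplitude, alpha, beta > 0 and t0 >= 0"
            )


def gamma_variate(t, p: KineticParams):
    """Peak-normalized gamma-variate bolus value at time(s) ``t``.

    ``amplitude * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)``
    for ``t > t0`` and 0 before arrival.  The peak equals ``amplitude`` at
    ``t = t0 + alpha * beta`` by construction.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    dt = t - p.t0
    with np.errstate(invalid="ignore"):
        val = np.where(
            dt > 0,
            p.amplitude
            * (np.maximum(dt, 0) / (p.alpha * p.beta)) ** p.alpha
            * np.exp(p.alpha - np.maximum(dt, 0) / p.beta),
            0.0,
        )
    return val if val.ndim else float(val)


def generate_aif_curve(
    p: KineticParams, frame_times: np.ndarray, baseline: float = 0.0
) -> TimeCurve:
    """Sample a blood-pool (AIF) curve on the given frame times.

    The number of frames strictly before the arrival time ``t0`` is
    recorded as the curve's baseline-frame count.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    if p.t0 >= frame_times[-1]:
        raise ValueError("bolus arrives after the last frame: degenerate curve")
    values = baseline + gamma_variate(frame_times, p)
    n_baseline = int(np.count_nonzero(frame_times < p.t0))
    return TimeCurve(frame_times, values, n_baseline=n_baseline)


def generate_tissue_curve(
    aif: TimeCurve,
    k: float,
    delay: float = 0.0,
    smoothing_width: int = 1,
    tissue_baseline: float = 0.0,
) -> TimeCurve:
    """Myocardial tissue curve with a known upslope transfer factor ``k``.

    The AIF enhancement (above its own pre-arrival baseline) is delayed,
    boxcar-smoothed over ``smoothing_width`` frames and scaled by ``k``;
    ``tissue_baseline`` is added back.  The delay is applied in whole
    frames (rounded to the nearest frame of the AIF's sampling grid) so
    that with ``smoothing_width = 1`` the tissue samples are exactly
    ``k``-scaled shifted AIF samples and every windowed OLS slope scales by
    ``k``.
    """
    if k <= 0:
        raise ValueError("transfer factor k must be positive")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    n = len(aif)
    if smoothing_width < 1 or smoothing_width > n:
        raise ValueError("smoothing width must be in [1, curve length]")
    frame_interval = float(np.median(np.diff(aif.times)))
    shift = int(round(delay / frame_interval))
    aif_base = aif.values[: aif.n_baseline].mean() if aif.n_baseline else aif.values[0]
    enh = aif.values - aif_base
    shifted = np.concatenate([np.zeros(shift), enh])[:n]
    if smoothing_width > 1:
        kernel = np.ones(smoothing_width) / smoothing_width
        padded = np.concatenate([np.zeros(smoothing_width - 1), shifted])
        shifted = np.convolve(padded, kernel, mode="valid")
    values = tissue_baseline + k * shifted
    n_baseline = min(aif.n_baseline + shift, n - 1)
    return TimeCurve(aif.times, values, n_baseline=n_baseline)
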