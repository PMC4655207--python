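"""Short-axis digital phantom rendering.

Each slice is an annular myocardium around a circular LV blood pool on a
square pixel grid.  Blood-pool pixels follow the arterial input function;
each AHA sector of the myocardium follows its own tissue curve with a
prescribed upslope transfer factor, so every analysis target has an
analytic ground truth.  Additive Gaussian pixel noise emulates acquisition
noise at the SNR of first-pass magnitude images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AHASegmentation,
    Contour,
    GeometryError,
    Level,
    aha_sector_masks,
    annulus_mask,
    contour_mask,
)
from .kinetics import generate_tissue_curve
from .perfusion import TimeCurve

__all__ = [
    "PhantomGeometry",
    "PerfusionSeries",
    "render_phantom_slice",
    "generate_lge_image",
    "make_annulus_contours",
]


@dataclass
class PhantomGeometry:
    """Geometry of one phantom slice.

    ``wall_thickness_px`` gives the wall thickness at ``n_contour_points``
    uniformly spaced angles in ``[-pi, pi)`` (package angle convention); a
    scalar means a uniform wall.
    """

    shape: tuple[int, int] = (64, 64)
    endo_radius_px: float = 12.0
    wall_thickness_px: np.ndarray | float = 4.0
    center: tuple[float, float] | None = None
    pixel_spacing_mm: float = 2.0
    slice_thickness_mm: float = 10.0
    n_contour_points: int = 96
    rv_insertion_angle: float = np.deg2rad(150.0)
    slice_index: int = 0
    slice_position_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.endo_radius_px <= 0:
            raise GeometryError("endocardial radius must be positive")
        if np.any(np.asarray(self.wall_thickness_px) <= 0):
            raise GeometryError("wall thickness must be positive")
        if self.center is None:
            self.center = ((self.shape[1] - 1) / 2.0, (self.shape[0] - 1) / 2.0)


@dataclass
class PerfusionSeries:
    """A timed short-axis dynamic image stack for one slice and one state."""

    frames: np.ndarray  # (t, ny, nx)
    times: np.ndarray
    n_baseline: int
    state: str = "rest"
    level: Level = "mid"
    slice_index: int = 0
    slice_position_mm: float = 0.0
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.size:
            raise ValueError("frames must be (t, ny, nx) matching times")


def make_annulus_contours(geom: PhantomGeometry) -> tuple[Contour, Contour]:
    """Endo/epicardial contours of the phantom annulus."""
    ang = np.linspace(-np.pi, np.pi, geom.n_contour_points, endpoint=False)
    thick = np.broadcast_to(np.asarray(geom.wall_thickness_px, float), ang.shape)
    cx, cy = geom.center
    r_en = np.full_like(ang, geom.endo_radius_px)
    r_ep = r_en + thick

    def _poly(r: np.ndarray) -> np.ndarray:
        return np.column_stack([cx + r * np.cos(ang), cy - r * np.sin(ang)])

    endo = Contour(_poly(r_en), geom.slice_index, geom.slice_position_mm)
    epi = Contour(_poly(r_ep), geom.slice_index, geom.slice_position_mm)
    return endo, epi


def render_phantom_slice(
    geom: PhantomGeometry,
    aif: TimeCurve,
    sector_factors: dict[int, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    level: Level = "mid",
    state: str = "rest",
    delay_s: float = 0.0,
    smoothing_width: int = 1,
    tissue_baseline: float = 0.05,
    background: float = 0.02,
    dtype=np.float32,
) -> tuple[PerfusionSeries, Contour, Contour, AHASegmentation]:
    """Render one dynamic phantom slice.

    ``sector_factors`` maps AHA segment ids at this level to the tissue
    transfer factor ``k``; blood-pool pixels follow the AIF.  Returns the
    series together with the true contours and the sector segmentation used
    for rendering.
    """
    endo, epi = make_annulus_contours(geom)
    seg = aha_sector_masks(endo, epi, geom.rv_insertion_angle, level, geom.shape)
    if set(sector_factors) != set(seg.segment_ids):
        raise ValueError(
            f"sector_factors must cover segments {seg.segment_ids} at level {level!r}"
        )
    n_t = len(aif)
    frames = np.full((n_t,) + tuple(geom.shape), background, dtype=float)
    pool = contour_mask(endo, geom.shape)
    frames[:, pool] = aif.values[:, None]
    for sid, k in sector_factors.items():
        tc = generate_tissue_curve(
            aif, k, delay=delay_s, smoothing_width=smoothing_width,
            tissue_baseline=tissue_baseline,
        )
        frames[:, seg.masks[sid]] = tc.values[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    series = PerfusionSeries(
        frames=frames.astype(dtype),
        times=aif.times.copy(),
        n_baseline=aif.n_baseline,
        state=state,
        level=level,
        slice_index=geom.slice_index,
        slice_position_mm=geom.slice_position_mm,
        pixel_spacing_mm=geom.pixel_spacing_mm,
    )
    return series, endo, epi, seg


def generate_lge_image(
    geom: PhantomGeometry,
    scar_mask: np.ndarray,
    remote_mean: float = 100.0,
    remote_sd: float = 5.0,
    scar_mean: float = 150.0,
    seed: int | None = None,
    blood_mean: float = 180.0,
    background: float = 10.0,
) -> np.ndarray:
    """Render one late-gadolinium-enhancement slice.

    Myocardial pixels are Normal(remote_mean, remote_sd) outside the scar
    and Normal(scar_mean, remote_sd) inside; the blood pool is bright, as
    after contrast.  ``scar_mask`` must lie within the myocardium.
    """
    if scar_mean <= remote_mean:
        raise ValueError("scar_mean must exceed remote_mean")
    endo, epi = make_annulus_contours(geom)
    myo = annulus_mask(endo, epi, geom.shape)
    scar = np.asarray(scar_mask, dtype=bool)
    if scar.shape != myo.shape:
        raise ValueError("scar mask shape mismatch")
    if np.any(scar & ~myo):
        raise ValueError("scar mask extends outside the myocardium")
    rng = np.random.default_rng(seed)
    img = np.full(geom.shape, background, dtype=float)
    img[contour_mask(endo, geom.shape)] = blood_mean
    mean_map = np.where(scar, scar_mean, remote_mean)
    if remote_sd > 0:
        img[myo] = rng.normal(mean_map[myo], remote_sd)
    else:
        img[myo] = mean_map[myo]
    return img


def scar_wedge_mask(
    geom: PhantomGeometry,
    segmentation: AHASegmentation,
    segment_id: int,
    angular_fraction: float = 0.6,
    transmural: tuple[float, float] = (0.3, 0.7),
) -> np.ndarray:
    """Mid-mural scar wedge nested inside one sector.

    Covers the central ``angular_fraction`` of the sector's angular span and
    the ``transmural`` depth range of the wall, so the wedge survives the
    10% transmural contraction applied during analysis.
    """
    endo, epi = make_annulus_contours(geom)
    sector = segmentation.masks[segment_id]
    cx, cy = geom.center
    yy, xx = np.nonzero(sector)
    theta = np.arctan2(-(yy - cy), xx - cx)
    r = np.hypot(xx - cx, yy - cy)
    c = np.array([cx, cy])
    r_en = endo.radii_at(theta, c)
    r_ep = epi.radii_at(theta, c)
    depth = (r - r_en) / np.maximum(r_ep - r_en, 1e-9)
    # central angular band of the sector
    span = 2.0 * np.pi / len(segmentation.masks)
    mean_vec = np.array([np.cos(theta).mean(), np.sin(theta).mean()])
    mid = np.arctan2(mean_vec[1], mean_vec[0])
    dphi = np.angle(np.exp(1j * (theta - mid)))
    keep = (
        (np.abs(dphi) <= angular_fraction * span / 2.0)
        & (depth >= transmural[0])
        & (depth <= transmural[1])
    )
    out = np.zeros(geom.shape, dtype=bool)
    out[yy[keep], xx[keep]] = True
    return out
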