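"""Late-gadolinium-enhancement (LGE) scar quantification.

Hyperenhanced myocardium is segmented by remote-referenced thresholding:
the remote (normal-appearing) region is estimated from the dimmer half of
the myocardium, iterated once after provisional scar removal, and scar is
everything brighter than ``remote_mean + c * remote_sd`` (default c = 5).
Optional linear partial-volume weighting credits boundary pixels a
fractional contribution between the remote and scar-core intensities.
The mean+SD rule is invariant to affine intensity transforms a*I + b
(a > 0), so absolute signal calibration does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

from .geometry import MYOCARDIAL_DENSITY_G_PER_ML, AHASegmentation

__all__ = [
    "ScarResult",
    "quantify_scar",
    "scar_percent_of_lvm",
    "segment_lge_status",
    "lge_area_percent",
]


@dataclass
class ScarResult:
    """Scar segmentation of one short-axis LGE slice."""

    scar_mask: np.ndarray
    scar_volume_ml: float
    remote_mean: float
    remote_sd: float
    threshold: float
    weighted_pixels: float = 0.0
    scar_percent_lvm: float = float("nan")


def quantify_scar(
    lge_image: np.ndarray,
    myocardium_mask: np.ndarray,
    pixel_spacing_mm: float = 1.0,
    slice_thickness_mm: float = 8.0,
    c: float = 5.0,
    min_size: int = 10,
    partial_volume: bool = True,
    exclude_mask: np.ndarray | None = None,
) -> ScarResult:
    """Segment hyperenhancement on one LGE slice.

    The remote region is first taken as myocardial pixels below the
    myocardial median intensity; after removing the provisional scar at
    ``remote_mean + c * remote_sd`` the remote estimate is recomputed once
    and the final threshold applied.  Connected components smaller than
    ``min_size`` pixels are discarded.  With ``partial_volume`` each scar
    pixel contributes a weight that rises linearly from 0 at the remote
    mean to 1 at the scar-core mean, clipped to [0, 1]; scar volume is the
    weighted pixel sum times the voxel volume.

    ``exclude_mask`` marks pixels to ignore entirely (the file-based
    stand-in for manual corrections).
    """
    myo = np.asarray(myocardium_mask, dtype=bool)
    if exclude_mask is not None:
        myo = myo & ~np.asarray(exclude_mask, bool)
    if not myo.any():
        raise ValueError("empty myocardium mask")
    img = np.asarray(lge_image, dtype=float)
    vals = img[myo]

    def _remote_stats(candidate: np.ndarray) -> tuple[float, float]:
        v = img[candidate]
        if v.size == 0:
            raise ValueError("empty remote reference region")
        below = candidate & (img <= np.median(v))
        rv = img[below]
        if rv.size < 2:
            raise ValueError("remote region too small")
        return float(rv.mean()), float(rv.std(ddof=1))

    rm, rs = _remote_stats(myo)
    provisional = myo & (img > rm + c * rs)
    rm, rs = _remote_stats(myo & ~provisional)
    thr = rm + c * rs
    scar = myo & (img > thr)

    if min_size > 1 and scar.any():
        lab = label(scar, connectivity=2)
        keep = np.zeros_like(scar)
        for region_id in range(1, lab.max() + 1):
            comp = lab == region_id
            if comp.sum() >= min_size:
                keep |= comp
        scar = keep

    voxel_ml = pixel_spacing_mm**2 * slice_thickness_mm / 1000.0
    if scar.any():
        core_mean = float(img[scar].mean())
        if partial_volume and core_mean > rm:
            w = np.clip((img[scar] - rm) / (core_mean - rm), 0.0, 1.0)
            weighted = float(w.sum())
        else:
            weighted = float(scar.sum())
    else:
        weighted = 0.0
    return ScarResult(
        scar_mask=scar,
        scar_volume_ml=weighted * voxel_ml,
        remote_mean=rm,
        remote_sd=rs,
        threshold=thr,
        weighted_pixels=weighted,
    )


def scar_percent_of_lvm(scar_volume_ml: float, lvm_g: float) -> float:
    """Scar mass as percent of LV mass (myocardial density 1.05 g/ml)."""
    if lvm_g <= 0:
        raise ValueError("LV mass must be positive")
    return 100.0 * scar_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML / lvm_g


def segment_lge_status(
    scar_mask: np.ndarray,
    segmentation: AHASegmentation,
    min_fraction: float = 0.05,
) -> dict[int, bool]:
    """Per-segment LGE+/LGE- flags.

    A segment is LGE+ when scar pixels make up at least ``min_fraction`` of
    its pixels.  Pass a segmentation matched to the LGE slice (see
    :func:`perfseg.geometry.match_slices`); unmatched slices should simply
    not be scored.
    """
    scar = np.asarray(scar_mask, bool)
    out: dict[int, bool] = {}
    for sid, m in segmentation.masks.items():
        n = m.sum()
        out[sid] = bool(n > 0 and (scar & m).sum() >= min_fraction * n)
    return out


def lge_area_percent(scar_mask: np.ndarray, annulus_mask: np.ndarray) -> float:
    """Scar area as percent of the slice myocardial (annulus) area."""
    ann = np.asarray(annulus_mask, bool)
    if not ann.any():
        raise ValueError("empty annulus mask")
    scar = np.asarray(scar_mask, bool) & ann
    return 100.0 * scar.sum() / ann.sum()
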