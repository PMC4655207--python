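"""Contour geometry for short-axis cardiac MR analysis.

Handles endo/epicardial contours, transmural contraction of the analyzed
annulus, AHA sector masks, wall-thickness profiles, LV volumes and mass,
body-surface-area indexing, and slice co-registration between image stacks.

Coordinate conventions
----------------------
Contour vertices are ``(x, y)`` in pixel coordinates with ``x`` rightward
and ``y`` downward (image convention); pixel centers sit at integer
coordinates.  Angles are measured *counterclockwise on the displayed image*
from the positive x axis, i.e. ``theta = atan2(cy - y, x - cx)``.  The RV
insertion angle recorded in a :class:`ContourSet` uses the same convention;
sector angles ``phi`` are measured counterclockwise from the insertion ray.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "Contour",
    "ContourSet",
    "AHASegmentation",
    "ThicknessProfile",
    "GeometryError",
    "contract_annulus",
    "aha_sector_masks",
    "wall_thickness_profile",
    "lv_volumes",
    "lv_mass",
    "bsa",
    "index_by_bsa",
    "match_slices",
    "annulus_mask",
    "contour_mask",
]

Level = Literal["basal", "mid", "apical"]

#: AHA segment ids per angular bin (counterclockwise from the anterior RV
#: insertion).  Basal/mid bins are 60 deg starting at the insertion; the
#: first bin is the basal anteroseptal segment (2), the last the basal
#: anterior segment (1).  Apical bins are 90 deg, rotated 45 deg from the
#: basal grid (first edge at phi = 15 deg), ordered septal, inferior,
#: lateral, anterior.
AHA_BIN_IDS = {
    "basal": (2, 3, 4, 5, 6, 1),
    "mid": (8, 9, 10, 11, 12, 7),
    "apical": (14, 15, 16, 13),
}
APICAL_OFFSET_DEG = 15.0


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent contour geometry."""


def _polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise vertex order."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return vertices.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Contour:
    """A closed simple polygon on one short-axis slice.

    Vertices are stored as an open ring (last vertex connects back to the
    first) in counterclockwise orientation, which is enforced on ingest.
    """

    vertices: np.ndarray
    slice_index: int = 0
    slice_position: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("contour needs >= 3 (x, y) vertices")
        if np.allclose(v[0], v[-1]) and v.shape[0] > 3:
            v = v[:-1]
        if _polygon_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    @property
    def area(self) -> float:
        """Enclosed area in px^2."""
        return abs(_polygon_area(self.vertices))

    @property
    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.vertices)

    def radii_at(self, angles: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
        """Boundary radius along rays from ``center`` at the given angles.

        Exact for star-convex contours up to linear interpolation between
        vertices in polar coordinates.  Angles follow the package convention
        (counterclockwise on the displayed image).
        """
        c = self.centroid if center is None else np.asarray(center, float)
        d = self.vertices - c
        theta = np.arctan2(-d[:, 1], d[:, 0])
        r = np.hypot(d[:, 0], d[:, 1])
        order = np.argsort(theta)
        theta, r = theta[order], r[order]
        return np.interp(angles, theta, r, period=2.0 * np.pi)


@dataclass
class ContourSet:
    """Endo/epicardial contour pairs for a short-axis stack.

    ``endo[i]`` must lie strictly inside ``epi[i]`` on every slice.
    """

    endo: list[Contour]
    epi: list[Contour]
    rv_insertion_angle: float = np.deg2rad(150.0)
    pixel_spacing: float = 1.0
    slice_thickness: float = 10.0
    phase: str = "ED"

    def __post_init__(self) -> None:
        if len(self.endo) != len(self.epi):
            raise GeometryError("endo/epi slice counts differ")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise GeometryError("pixel spacing and slice thickness must be positive")
        for en, ep in zip(self.endo, self.epi):
            ang = np.linspace(-np.pi, np.pi, 90, endpoint=False)
            c = ep.centroid
            if np.any(en.radii_at(ang, c) >= ep.radii_at(ang, c)):
                raise GeometryError("endocardium not strictly inside epicardium")

    @property
    def n_slices(self) -> int:
        return len(self.endo)

    @property
    def slice_positions(self) -> list[float]:
        return [c.slice_position for c in self.endo]


@dataclass
class AHASegmentation:
    """Labeled AHA sector masks over the (contracted) myocardial annulus."""

    level: Level
    masks: dict[int, np.ndarray]
    annulus: np.ndarray = field(repr=False, default=None)

    @property
    def segment_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.masks))

    def label_map(self) -> np.ndarray:
        out = np.zeros(self.annulus.shape, dtype=np.int16)
        for sid, m in self.masks.items():
            out[m] = sid
        return out


@dataclass
class ThicknessProfile:
    """Wall thickness (mm) per angular position, with IVS/PW maxima."""

    angles: np.ndarray
    thickness: np.ndarray
    max_ivs: float
    max_pw: float


def contour_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a contour to a boolean mask (pixel-center-in-polygon)."""
    poly_rc = contour.vertices[:, ::-1]  # polygon2mask expects (row, col)
    return polygon2mask(shape, poly_rc)


def annulus_mask(endo: Contour, epi: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Myocardial annulus mask: inside epi, outside endo."""
    return contour_mask(epi, shape) & ~contour_mask(endo, shape)


def contract_annulus(
    endo: Contour, epi: Contour, fraction: float = 0.10, n_points: int = 360
) -> tuple[Contour, Contour]:
    """Contract the analyzed wall transmurally by ``fraction`` on each side.

    Along each radial ray from the annulus centroid the analyzed wall is
    restricted to transmural depths ``[fraction, 1 - fraction]``; with the
    default 0.10 this discards 10% of the wall both endo- and epicardially
    to suppress partial-volume contamination from blood pool and
    surrounding tissue.

    Returns a new (endo, epi) contour pair resampled on ``n_points`` rays.
    ``fraction = 0`` returns the input contours unchanged.
    """
    if not 0.0 <= fraction < 0.5:
        raise GeometryError("contraction fraction must lie in [0, 0.5)")
    if fraction == 0.0:
        return endo, epi
    c = endo.centroid
    ang = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    r_en = endo.radii_at(ang, c)
    r_ep = epi.radii_at(ang, c)
    if np.any(r_ep <= r_en) or np.any(r_en <= 0):
        raise GeometryError("rays fail to intersect a proper annulus")
    wall = r_ep - r_en
    r_in = r_en + fraction * wall
    r_out = r_en + (1.0 - fraction) * wall

    def _poly(r: np.ndarray) -> np.ndarray:
        return np.column_stack([c[0] + r * np.cos(ang), c[1] - r * np.sin(ang)])

    mk = lambda r: Contour(_poly(r), endo.slice_index, endo.slice_position)
    return mk(r_in), mk(r_out)


def sector_angle_bins(level: Level) -> tuple[np.ndarray, tuple[int, ...]]:
    """Bin start angles (rad, relative to RV insertion) and AHA ids."""
    ids = AHA_BIN_IDS[level]
    n = len(ids)
    offset = np.deg2rad(APICAL_OFFSET_DEG) if level == "apical" else 0.0
    edges = offset + np.arange(n) * (2.0 * np.pi / n)
    return edges, ids


def aha_sector_masks(
    endo: Contour,
    epi: Contour,
    rv_insertion_angle: float,
    level: Level,
    shape: tuple[int, int],
) -> AHASegmentation:
    """Partition the annulus between ``endo`` and ``epi`` into AHA sectors.

    Pass the *contracted* contour pair to segment the analyzed annulus.
    Six 60-deg sectors at basal and midventricular levels, four 90-deg
    sectors (rotated 45 deg) apically; pixels are assigned by the angle of
    their center about the annulus centroid, measured counterclockwise from
    the RV insertion ray.  The sector masks are pairwise disjoint and their
    union equals the annulus mask exactly.
    """
    ann = annulus_mask(endo, epi, shape)
    if not ann.any():
        raise GeometryError("degenerate annulus: empty mask")
    _, ids = sector_angle_bins(level)
    n = len(ids)
    offset = np.deg2rad(APICAL_OFFSET_DEG) if level == "apical" else 0.0
    c = endo.centroid
    yy, xx = np.nonzero(ann)
    theta = np.arctan2(-(yy - c[1]), xx - c[0])
    phi = np.mod(theta - rv_insertion_angle - offset, 2.0 * np.pi)
    bins = np.minimum((phi / (2.0 * np.pi / n)).astype(int), n - 1)
    masks: dict[int, np.ndarray] = {}
    for j, sid in enumerate(ids):
        m = np.zeros(shape, dtype=bool)
        m[yy[bins == j], xx[bins == j]] = True
        masks[sid] = m
    return AHASegmentation(level=level, masks=masks, annulus=ann)


def wall_thickness_profile(
    endo: Contour,
    epi: Contour,
    n_rays: int = 90,
    pixel_spacing: float = 1.0,
    rv_insertion_angle: float = np.deg2rad(150.0),
    ivs_window_deg: tuple[float, float] = (60.0, 180.0),
    pw_window_deg: tuple[float, float] = (240.0, 300.0),
) -> ThicknessProfile:
    """Radial wall thickness in mm on ``n_rays`` rays from the centroid.

    ``max_ivs`` / ``max_pw`` are maxima over the configured angular windows
    (degrees counterclockwise from the RV insertion ray); the defaults place
    the interventricular septum at 60-180 deg and the posterior wall at
    240-300 deg.
    """
    if n_rays < 8:
        raise GeometryError("need at least 8 rays")
    c = endo.centroid
    ang = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
    r_en = endo.radii_at(ang, c)
    r_ep = epi.radii_at(ang, c)
    thick = (r_ep - r_en) * pixel_spacing
    bad = thick < 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} rays missed an intersection; excluded")
        thick = np.where(bad, np.nan, thick)
    phi = np.rad2deg(np.mod(ang - rv_insertion_angle, 2.0 * np.pi))

    def _window_max(lo: float, hi: float) -> float:
        sel = (phi >= lo) & (phi < hi)
        vals = thick[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")

    return ThicknessProfile(
        angles=ang,
        thickness=thick,
        max_ivs=_window_max(*ivs_window_deg),
        max_pw=_window_max(*pw_window_deg),
    )


def _cavity_volume_ml(cs: ContourSet) -> float:
    area_px = sum(c.area for c in cs.endo)
    return area_px * cs.pixel_spacing**2 * cs.slice_thickness / 1000.0


def lv_volumes(ed: ContourSet, es: ContourSet) -> tuple[float, float, float, float]:
    """Planimetric LV volumes and ejection fraction.

    Cavity volume is the summed endocardial area times slice thickness
    (Simpson's rule over the short-axis stack).  Returns
    ``(EDV, ESV, SV, EF)`` with volumes in ml and EF in percent:
    ``SV = EDV - ESV``, ``EF = 100 * SV / EDV``.
    """
    if ed.n_slices != es.n_slices:
        raise GeometryError("ED/ES slice counts differ")
    edv = _cavity_volume_ml(ed)
    esv = _cavity_volume_ml(es)
    if edv <= 0:
        raise GeometryError("EDV is zero; ejection fraction undefined")
    sv = edv - esv
    return edv, esv, sv, 100.0 * sv / edv


MYOCARDIAL_DENSITY_G_PER_ML = 1.05


def lv_mass(contours: ContourSet) -> float:
    """LV mass in grams: planimetric myocardial volume times 1.05 g/ml."""
    vol_ml = 0.0
    for en, ep in zip(contours.endo, contours.epi):
        a = ep.area - en.area
        if a < 0:
            raise GeometryError("negative annulus area on a slice")
        vol_ml += a * contours.pixel_spacing**2 * contours.slice_thickness / 1000.0
    return vol_ml * MYOCARDIAL_DENSITY_G_PER_ML


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 (Mosteller default, DuBois optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm**0.725 * weight_kg**0.425)
    raise ValueError(f"unknown BSA formula: {formula!r}")


def index_by_bsa(value: float, bsa_m2: float) -> float:
    """Index a volume/mass by body surface area (per m^2)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    return value / bsa_m2


def match_slices(
    positions_a: Sequence[float],
    positions_b: Sequence[float],
    tolerance: float = 5.0,
) -> list[tuple[int, int]]:
    """Greedy nearest-position pairing of two slice stacks.

    Pairs are formed closest-first; each slice is used at most once and
    pairs farther apart than ``tolerance`` (mm) are left unpaired, which
    mirrors incomplete coverage between acquisitions.
    """
    a = np.asarray(positions_a, float)
    b = np.asarray(positions_b, float)
    if a.size == 0 or b.size == 0:
        return []
    dist = np.abs(a[:, None] - b[None, :])
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in order:
        if dist[i, j] > tolerance:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j)))
        used_a.add(int(i))
        used_b.add(int(j))
    return sorted(pairs)
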