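"""Disk round-trip for synthetic subjects.

Per subject: ``<id>_rest.nii.gz`` / ``<id>_stress.nii.gz`` (4-D x, y,
slice, time), ``<id>_lge.nii.gz`` (3-D), ``<id>_contours.json``,
``<id>_truth.json`` plus ``<id>_truthmasks.nii.gz`` (bit 1 = hypoperfused,
bit 2 = scar), and a cohort ``manifest.csv``.  All writers are
byte-deterministic for a fixed cohort, so identical seed and configuration
reproduce identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import (
    LEVELS,
    CohortConfig,
    GroundTruth,
    SubjectDataset,
    generate_cohort,
)
from .geometry import Contour, ContourSet
from .phantom import PerfusionSeries

__all__ = [
    "write_subject",
    "load_subject",
    "simulate_to_dir",
    "load_cohort",
]


def _affine(pixel_spacing: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def _series_to_4d(series: dict[str, PerfusionSeries]) -> np.ndarray:
    # frames are (t, y, x); NIfTI wants (x, y, z, t)
    vols = [np.transpose(series[lvl].frames, (2, 1, 0)) for lvl in LEVELS]
    return np.stack(vols, axis=2).astype(np.float32)


def _contour_to_json(c: Contour) -> dict:
    return {
        "slice_index": c.slice_index,
        "slice_position_mm": c.slice_position,
        "vertices": np.round(c.vertices, 4).tolist(),
    }


def _contourset_to_json(cs: ContourSet) -> dict:
    return {
        "phase": cs.phase,
        "pixel_spacing_mm": cs.pixel_spacing,
        "slice_thickness_mm": cs.slice_thickness,
        "rv_insertion_deg": float(np.rad2deg(cs.rv_insertion_angle)),
        "slices": [
            {
                "slice_position_mm": en.slice_position,
                "slice_index": en.slice_index,
                "endo": _contour_to_json(en)["vertices"],
                "epi": _contour_to_json(ep)["vertices"],
            }
            for en, ep in zip(cs.endo, cs.epi)
        ],
    }


def _contourset_from_json(d: dict) -> ContourSet:
    endo, epi = [], []
    for s in d["slices"]:
        endo.append(Contour(np.array(s["endo"]), s["slice_index"], s["slice_position_mm"]))
        epi.append(Contour(np.array(s["epi"]), s["slice_index"], s["slice_position_mm"]))
    return ContourSet(
        endo=endo,
        epi=epi,
        rv_insertion_angle=np.deg2rad(d["rv_insertion_deg"]),
        pixel_spacing=d["pixel_spacing_mm"],
        slice_thickness=d["slice_thickness_mm"],
        phase=d["phase"],
    )


def write_subject(ds: SubjectDataset, outdir: str | Path) -> dict[str, Path]:
    """Write one subject's images, contours and ground truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = ds.subject_id
    spacing = ds.perfusion_contours.pixel_spacing
    paths: dict[str, Path] = {}

    for state, series in (("rest", ds.rest_series), ("stress", ds.stress_series)):
        p = outdir / f"{sid}_{state}.nii.gz"
        nib.save(
            nib.Nifti1Image(_series_to_4d(series), _affine(spacing, 10.0)), p
        )
        paths[state] = p

    lge = np.stack(
        [np.transpose(ds.lge_stack[lvl], (1, 0)) for lvl in LEVELS], axis=2
    ).astype(np.float32)
    paths["lge"] = outdir / f"{sid}_lge.nii.gz"
    nib.save(nib.Nifti1Image(lge, _affine(spacing, 8.0)), paths["lge"])

    gt = ds.ground_truth
    bits = np.stack(
        [
            np.transpose(
                gt.hypoperfused_mask[lvl].astype(np.int8)
                + 2 * gt.scar_mask[lvl].astype(np.int8),
                (1, 0),
            )
            for lvl in LEVELS
        ],
        axis=2,
    )
    paths["truthmasks"] = outdir / f"{sid}_truthmasks.nii.gz"
    nib.save(nib.Nifti1Image(bits, _affine(spacing, 10.0)), paths["truthmasks"])

    contours = {
        "cine_ED": _contourset_to_json(ds.cine_contours["ED"]),
        "cine_ES": _contourset_to_json(ds.cine_contours["ES"]),
        "perfusion": _contourset_to_json(ds.perfusion_contours),
        "lge": _contourset_to_json(ds.lge_contours),
    }
    paths["contours"] = outdir / f"{sid}_contours.json"
    paths["contours"].write_text(json.dumps(contours, sort_keys=True))

    truth = {
        "perfusion_factors": {
            lvl: {str(k): list(v) for k, v in gt.perfusion_factors[lvl].items()}
            for lvl in LEVELS
        },
        "thickness_profile_mm": {
            lvl: np.round(gt.thickness_profile_mm[lvl], 4).tolist() for lvl in LEVELS
        },
        "lvh_segments": [[lvl, sid_] for lvl, sid_ in gt.lvh_segments],
        "scar_segments": [[lvl, sid_] for lvl, sid_ in gt.scar_segments],
        "timing": {
            "times": ds.rest_series[LEVELS[0]].times.tolist(),
            "n_baseline": ds.rest_series[LEVELS[0]].n_baseline,
        },
        "meta": {
            "subject_id": sid,
            "group": ds.group,
            "age": ds.age,
            "height": ds.height,
            "weight": ds.weight,
            "seed": ds.seed,
        },
    }
    paths["truth"] = outdir / f"{sid}_truth.json"
    paths["truth"].write_text(json.dumps(truth, sort_keys=True))
    return paths


def load_subject(outdir: str | Path, subject_id: str) -> SubjectDataset:
    """Reload one subject written by :func:`write_subject`."""
    outdir = Path(outdir)
    truth = json.loads((outdir / f"{subject_id}_truth.json").read_text())
    contours = json.loads((outdir / f"{subject_id}_contours.json").read_text())
    perf_cs = _contourset_from_json(contours["perfusion"])
    times = np.asarray(truth["timing"]["times"], float)
    n_baseline = int(truth["timing"]["n_baseline"])
    spacing = perf_cs.pixel_spacing

    def _load_series(state: str) -> dict[str, PerfusionSeries]:
        arr = np.asanyarray(nib.load(outdir / f"{subject_id}_{state}.nii.gz").dataobj)
        out = {}
        for z, lvl in enumerate(LEVELS):
            frames = np.transpose(arr[:, :, z, :], (2, 1, 0))
            out[lvl] = PerfusionSeries(
                frames=frames,
                times=times,
                n_baseline=n_baseline,
                state=state,
                level=lvl,
                slice_index=z,
                slice_position_mm=perf_cs.endo[z].slice_position,
                pixel_spacing_mm=spacing,
            )
        return out

    lge_arr = np.asanyarray(nib.load(outdir / f"{subject_id}_lge.nii.gz").dataobj)
    lge_stack = {
        lvl: np.transpose(lge_arr[:, :, z], (1, 0)) for z, lvl in enumerate(LEVELS)
    }
    bits = np.asanyarray(nib.load(outdir / f"{subject_id}_truthmasks.nii.gz").dataobj)
    hypo = {lvl: np.transpose(bits[:, :, z] & 1, (1, 0)).astype(bool)
            for z, lvl in enumerate(LEVELS)}
    scar = {lvl: np.transpose((bits[:, :, z] >> 1) & 1, (1, 0)).astype(bool)
            for z, lvl in enumerate(LEVELS)}

    meta = truth["meta"]
    gt = GroundTruth(
        perfusion_factors={
            lvl: {int(k): tuple(v) for k, v in truth["perfusion_factors"][lvl].items()}
            for lvl in LEVELS
        },
        scar_mask=scar,
        hypoperfused_mask=hypo,
        thickness_profile_mm={
            lvl: np.asarray(truth["thickness_profile_mm"][lvl]) for lvl in LEVELS
        },
        lvh_segments=[(l, s) for l, s in truth["lvh_segments"]],
        scar_segments=[(l, s) for l, s in truth["scar_segments"]],
    )
    return SubjectDataset(
        subject_id=meta["subject_id"],
        group=meta["group"],
        age=meta["age"],
        height=meta["height"],
        weight=meta["weight"],
        rest_series=_load_series("rest"),
        stress_series=_load_series("stress"),
        lge_stack=lge_stack,
        cine_contours={
            "ED": _contourset_from_json(contours["cine_ED"]),
            "ES": _contourset_from_json(contours["cine_ES"]),
        },
        perfusion_contours=perf_cs,
        lge_contours=_contourset_from_json(contours["lge"]),
        ground_truth=gt,
        seed=meta["seed"],
    )


def simulate_to_dir(config: CohortConfig, outdir: str | Path) -> Path:
    """Generate the configured cohort and write it (plus manifest) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = generate_cohort(config)
    rows = []
    for ds in subjects:
        write_subject(ds, outdir)
        rows.append(
            {
                "subject_id": ds.subject_id,
                "group": ds.group,
                "age": round(ds.age, 2),
                "height_cm": round(ds.height, 1),
                "weight_kg": round(ds.weight, 1),
                "seed": ds.seed,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (outdir / "cohort_config.yaml").write_text(
        yaml.safe_dump({**config.params, "seed": config.seed}, sort_keys=True)
    )
    return manifest


def load_cohort(outdir: str | Path) -> list[SubjectDataset]:
    """Reload every subject listed in a simulation directory's manifest."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    return [load_subject(outdir, sid) for sid in manifest["subject_id"]]
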