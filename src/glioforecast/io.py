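"""NIfTI and manifest I/O for longitudinal patient datasets.

A patient is stored as one manifest (YAML or JSON) listing the visits —
time in days plus one NIfTI file per sequence/mask — and the treatment
schedules.  All volumes of a patient must share one grid; images are kept
in their native index space (no resampling).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    CellularityParams,
    ImageGrid,
    ImagingVisit,
    PatientDataset,
    measured_cellularity,
)
from .errors import GridMismatchError, ManifestError
from .therapy import TreatmentSchedule

_VISIT_KEYS = (
    "adc", "t1_pre", "t1_post",
    "enhancing_mask", "nonenhancing_mask", "brain_mask", "tissue_labels",
)
_MASK_KEYS = {"enhancing_mask", "nonenhancing_mask", "brain_mask"}


def write_nifti(data: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    """Write a volume on ``grid`` as NIfTI, preserving dtype."""
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_data_dtype(np.asarray(data).dtype)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    grid = ImageGrid(
        shape=tuple(int(n) for n in data.shape[:3]),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        origin=tuple(float(o) for o in aff[:3, 3]),
    )
    return data, grid


def _schedule_to_dict(s: TreatmentSchedule | None) -> dict | None:
    if s is None:
        return None
    d = {"kind": s.kind, "days": [float(x) for x in s.days]}
    if s.dose is not None:
        d["dose"] = [float(x) for x in s.dose]
    return d


def _schedule_from_dict(d: dict | None) -> TreatmentSchedule | None:
    if d is None:
        return None
    return TreatmentSchedule(
        kind=d["kind"], days=tuple(d["days"]),
        dose=tuple(d["dose"]) if d.get("dose") is not None else None,
    )


def write_dataset(
    dataset: PatientDataset, outdir: str | Path, manifest_name: str = "manifest.yaml"
) -> Path:
    """Write all visit volumes plus the manifest; returns the manifest path.

    Continuous images are stored as float64 and masks/labels as uint8, so a
    write -> read round trip reproduces every array bit-exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = dataset.grid
    visits_meta = []
    for i, v in enumerate(dataset.visits):
        entry: dict = {"time_days": float(v.time)}
        for key in _VISIT_KEYS:
            arr = getattr(v, key)
            if key in _MASK_KEYS:
                arr = arr.astype(np.uint8)
            elif key == "tissue_labels":
                arr = arr.astype(np.uint8)
            else:
                arr = arr.astype(np.float64)
            fname = f"visit{i:02d}_{key}.nii.gz"
            write_nifti(arr, grid, outdir / fname)
            entry[key] = fname
        visits_meta.append(entry)
    manifest = {
        "patient_id": dataset.patient_id,
        "visits": visits_meta,
        "rt_schedule": _schedule_to_dict(dataset.rt_schedule),
        "ct_schedule": _schedule_to_dict(dataset.ct_schedule),
    }
    path = outdir / manifest_name
    if path.suffix == ".json":
        path.write_text(json.dumps(manifest, indent=2))
    else:
        path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_dataset(manifest_path: str | Path) -> PatientDataset:
    """Load a patient dataset from its manifest.

    Visits are returned sorted by time regardless of manifest order.
    Raises :class:`ManifestError` for missing keys/files and
    :class:`GridMismatchError` when a volume disagrees with the patient grid.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    text = manifest_path.read_text()
    manifest = json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(manifest, dict) or "visits" not in manifest:
        raise ManifestError(f"manifest {manifest_path} has no 'visits' section")

    base = manifest_path.parent
    grid: ImageGrid | None = None
    visits: list[ImagingVisit] = []
    for i, entry in enumerate(manifest["visits"]):
        missing = [k for k in ("time_days", *_VISIT_KEYS) if k not in entry]
        if missing:
            raise ManifestError(
                f"visit {i} (time={entry.get('time_days', '?')}) is missing keys: {missing}"
            )
        fields = {}
        for key in _VISIT_KEYS:
            fpath = base / entry[key]
            if not fpath.exists():
                raise ManifestError(f"visit {i}: file for '{key}' not found: {fpath}")
            data, g = read_nifti(fpath)
            if grid is None:
                grid = g
            elif not grid.matches(g):
                raise GridMismatchError(
                    f"volume '{entry[key]}' (shape {g.shape}, spacing {g.spacing}) "
                    f"does not match the patient grid {grid.shape}/{grid.spacing}"
                )
            if key in _MASK_KEYS:
                data = data.astype(bool)
            elif key == "tissue_labels":
                data = data.astype(np.uint8)
            else:
                data = data.astype(np.float64)
            fields[key] = data
        visits.append(ImagingVisit(grid=grid, time=float(entry["time_days"]), **fields))

    visits.sort(key=lambda v: v.time)
    dataset = PatientDataset(
        patient_id=str(manifest.get("patient_id", manifest_path.stem)),
        visits=visits,
        rt_schedule=_schedule_from_dict(manifest.get("rt_schedule")),
        ct_schedule=_schedule_from_dict(manifest.get("ct_schedule")),
    )
    dataset.validate()
    return dataset


def dataset_summary(
    dataset: PatientDataset, cellularity: CellularityParams | None = None
) -> pd.DataFrame:
    """Per-visit scalar summaries (volumes in mm^3, mean tumor ADC)."""
    cellularity = cellularity or CellularityParams()
    voxvol = dataset.grid.voxel_volume
    rows = []
    for v in dataset.visits:
        enh = v.enhancing_mask.astype(bool)
        non = v.nonenhancing_mask.astype(bool)
        union = enh | non
        meas = measured_cellularity(v, cellularity)
        rows.append(
            {
                "time_days": v.time,
                "enhancing_volume_mm3": float(enh.sum()) * voxvol,
                "nonenhancing_volume_mm3": float(non.sum()) * voxvol,
                "total_volume_mm3": float(union.sum()) * voxvol,
                "mean_tumor_adc": float(v.adc[union].mean()) if union.any() else np.nan,
                "cell_count": float(meas.sum()) * voxvol,
            }
        )
    return pd.DataFrame(rows)
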