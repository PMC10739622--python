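"""File formats: 4D NIfTI-1 dynamic series with a JSON frame-schedule sidecar,
input-function CSV, region-label NIfTI with a JSON label table."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicImage, FrameSchedule, InputFunction, RegionMap

__all__ = [
    "write_dynamic",
    "read_dynamic",
    "write_aif",
    "read_aif",
    "write_region_map",
    "read_region_map",
]


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_dynamic(img: DynamicImage, path):
    """4D NIfTI plus a {"frame_start_min", "frame_end_min"} JSON sidecar."""
    nib.save(nib.Nifti1Image(img.frames.astype(np.float32), _affine(img.voxel_size)), str(path))
    sidecar = {
        "frame_start_min": img.schedule.start.tolist(),
        "frame_end_min": img.schedule.end.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_dynamic(path) -> DynamicImage:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing frame-schedule sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for key in ("frame_start_min", "frame_end_min"):
        if key not in sidecar:
            raise ValueError(f"sidecar {sc_path} lacks required field {key!r}")
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D image")
    n_sidecar = len(sidecar["frame_start_min"])
    if data.shape[-1] != n_sidecar:
        raise ValueError(
            f"{path} has {data.shape[-1]} frames but sidecar {sc_path} lists {n_sidecar}"
        )
    if not np.isfinite(data).all():
        raise ValueError(f"{path} contains non-finite voxels")
    schedule = FrameSchedule(
        np.asarray(sidecar["frame_start_min"], dtype=float),
        np.asarray(sidecar["frame_end_min"], dtype=float),
    )
    voxel_size = tuple(float(v) for v in nii.header.get_zooms()[:3])
    return DynamicImage(data, schedule, voxel_size)


def write_aif(aif: InputFunction, path):
    pd.DataFrame({"time_min": aif.time, "cp_Bq_per_mL": aif.cp}).to_csv(path, index=False)


def read_aif(path) -> InputFunction:
    df = pd.read_csv(path)
    for col in ("time_min", "cp_Bq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")
    return InputFunction(df["time_min"].to_numpy(), df["cp_Bq_per_mL"].to_numpy())


def write_region_map(regions: RegionMap, path):
    nib.save(
        nib.Nifti1Image(regions.labels.astype(np.int16), _affine(regions.voxel_size)),
        str(path),
    )
    table = {str(k): v for k, v in regions.region_names.items()}
    _sidecar_path(path).write_text(json.dumps(table))


def read_region_map(path) -> RegionMap:
    path = Path(path)
    nii = nib.load(str(path))
    labels = np.asanyarray(nii.dataobj).astype(np.int16)
    sc_path = _sidecar_path(path)
    names = {}
    if sc_path.exists():
        names = {int(k): v for k, v in json.loads(sc_path.read_text()).items()}
    voxel_size = tuple(float(v) for v in nii.header.get_zooms()[:3])
    return RegionMap(labels, voxel_size, names)
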