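"""NIfTI-1 round-tripping of runs and maps, with JSON sidecars.

Runs are stored as 4-D NIfTI images in (x, y, z, t) order with the voxel
sizes on the affine diagonal; acquisition metadata the NIfTI header cannot
carry (modality, per-frame control/tag roles, frame times) goes in a JSON
sidecar next to the image.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .synth import Run

__all__ = ["save_run", "load_run", "save_volume", "load_volume", "sidecar_path"]


def sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_run(r: Run, path, extra_meta: dict | None = None) -> Path:
    """Write a run as 4-D NIfTI plus a JSON sidecar; returns the image path."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.transpose(r.data, (1, 2, 3, 0)).astype(np.float32),
        _affine(r.voxel_size),
    )
    img.header.set_zooms((*r.voxel_size, r.tr))
    nib.save(img, str(path))
    meta = {
        "tr": float(r.tr),
        "modality": r.modality,
        "frame_roles": [str(x) for x in r.frame_roles],
        "frame_times": [float(t) for t in r.frame_times],
        "voxel_size": [float(v) for v in r.voxel_size],
        **(extra_meta or {}),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_run(path) -> Run:
    """Read a run written by :func:`save_run`."""
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(sidecar_path(path).read_text())
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 0, 1, 2))
    return Run(
        data=data,
        tr=meta["tr"],
        modality=meta["modality"],
        frame_roles=np.array(meta["frame_roles"]),
        frame_times=np.array(meta["frame_times"]),
        voxel_size=tuple(meta["voxel_size"]),
    )


def save_volume(vol: np.ndarray, path, voxel_size=(3.75, 3.75, 6.0)) -> Path:
    """Write a 3-D volume (mask, p-value map, weight map) as NIfTI-1."""
    path = Path(path)
    vol = np.asarray(vol)
    dtype = np.uint8 if vol.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(vol.astype(dtype), _affine(voxel_size)), str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
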