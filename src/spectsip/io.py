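"""File containers: HDF5 for projection sets, NIfTI for volumes.

HDF5 layout: datasets ``/counts`` (A x N x N), ``/angles_deg``,
``/indices``; root attributes ``pixel_size_mm`` and ``count_scale``.
Counts round-trip bit-exactly (stored as float64 without compression
filters that would change values).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .core import Volume
from .projector import ProjectionSet


def save_projections(path, proj: ProjectionSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=proj.counts)
        f.create_dataset("angles_deg", data=proj.angles_deg)
        f.create_dataset("indices", data=proj.indices)
        f.attrs["pixel_size_mm"] = proj.pixel_size_mm
        f.attrs["count_scale"] = proj.count_scale


def load_projections(path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        return ProjectionSet(
            counts=f["counts"][()],
            indices=f["indices"][()],
            angles_deg=f["angles_deg"][()],
            pixel_size_mm=float(f.attrs["pixel_size_mm"]),
            count_scale=float(f.attrs["count_scale"]),
        )


def save_volume(path, vol: Volume) -> None:
    affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_volume(path, role: str = "reconstruction") -> Volume:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return Volume(np.maximum(np.asarray(img.dataobj, dtype=np.float64), 0.0), voxel, role)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
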