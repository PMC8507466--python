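"""Core containers shared across the toolkit.

The central object is :class:`Volume`, a cubic-in-plane 3D grid of
non-negative reals with a physical voxel size. Volumes play one of three
roles: an *activity* distribution (arbitrary units per voxel), an
*attenuation* map (linear attenuation coefficient, mm^-1), or a
*reconstruction* (OSEM output, count-scaled activity units).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

VOLUME_ROLES = ("activity", "attenuation", "reconstruction")


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateDataError(ValueError):
    """Data is formally valid but statistically degenerate (e.g. zero variance)."""


@dataclass
class Volume:
    """3D grid of non-negative reals with isotropic voxel size.

    Axis convention is ``(z, y, x)``: axis 0 is axial, axes 1-2 span the
    transaxial plane and must have equal length (rotation happens in-plane).
    """

    values: np.ndarray
    voxel_size_mm: float
    role: str = "activity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"Volume must be 3D, got ndim={self.values.ndim}")
        if self.values.shape[1] != self.values.shape[2]:
            raise ValidationError(
                f"transaxial dimensions must be equal, got {self.values.shape}"
            )
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        if self.role not in VOLUME_ROLES:
            raise ValidationError(f"unknown volume role {self.role!r}")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.role} volume contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Volume":
        return Volume(values, self.voxel_size_mm, role if role is not None else self.role)

    def copy(self) -> "Volume":
        return replace(self, values=self.values.copy())


def voxel_center_coords_mm(n: int, voxel_size_mm: float) -> np.ndarray:
    """Physical coordinates of voxel centers along one axis, centered on 0."""
    return (np.arange(n) - (n - 1) / 2.0) * voxel_size_mm
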