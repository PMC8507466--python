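"""Post-reconstruction smoothing filters for the comparison arms.

Two classic nuclear-medicine post-filters: an isotropic spatial-domain
Gaussian (SD given in mm) and a radially symmetric frequency-domain
Butterworth low-pass. The Butterworth magnitude response defaults to the
square-root form

    H(f) = (1 + (f/f_c)^(2n))^(-1/2)

(gain 1/sqrt(2) at cutoff); the power form 1/(1 + (f/f_c)^(2n)), common on
vendor consoles, is selectable. Cutoff units default to cycles/mm, with
cycles/pixel and fraction-of-Nyquist switches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ValidationError, Volume


@dataclass
class FilterSpec:
    kind: str = "gaussian"  # {"gaussian", "butterworth"}
    gaussian_sd_mm: float = 4.0
    bw_order: int = 2
    bw_cutoff: float = 0.036
    cutoff_units: str = "cycles_per_mm"  # {cycles_per_mm, cycles_per_pixel, fraction_of_nyquist}
    bw_form: str = "sqrt"  # {"sqrt", "power"}

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "butterworth"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.gaussian_sd_mm < 0:
            raise ValidationError("gaussian_sd_mm must be non-negative")
        if self.bw_order < 1:
            raise ValidationError("bw_order must be >= 1")
        if self.bw_cutoff <= 0:
            raise ValidationError("bw_cutoff must be positive")
        if self.cutoff_units not in (
            "cycles_per_mm",
            "cycles_per_pixel",
            "fraction_of_nyquist",
        ):
            raise ValidationError(f"unknown cutoff_units {self.cutoff_units!r}")
        if self.bw_form not in ("sqrt", "power"):
            raise ValidationError(f"unknown bw_form {self.bw_form!r}")


def butterworth_gain(f: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Magnitude response at radial frequency ``f`` (in the configured units)."""
    ratio = (np.asarray(f, dtype=np.float64) / spec.bw_cutoff) ** (2 * spec.bw_order)
    if spec.bw_form == "sqrt":
        return (1.0 + ratio) ** -0.5
    return 1.0 / (1.0 + ratio)


def gaussian_postfilter(vol: Volume, spec: FilterSpec) -> Volume:
    """Isotropic 3D Gaussian smoothing with sigma = sd_mm / voxel_size voxels.

    Edge handling renormalizes the kernel by its in-bounds mass, so the
    total voxel sum of interior-supported volumes is preserved.
    """
    if spec.gaussian_sd_mm < 0:
        raise ValidationError("gaussian_sd_mm must be non-negative")
    if spec.gaussian_sd_mm == 0:
        return vol.copy()
    sigma = spec.gaussian_sd_mm / vol.voxel_size_mm
    num = ndimage.gaussian_filter(vol.values, sigma, mode="constant")
    den = ndimage.gaussian_filter(np.ones_like(vol.values), sigma, mode="constant")
    return vol.with_values(num / den, role="reconstruction")


def butterworth_postfilter(vol: Volume, spec: FilterSpec) -> Volume:
    """Radial 3D Butterworth low-pass in the frequency domain.

    The zero-frequency (DC) component has gain exactly 1, so constant
    volumes pass unchanged.
    """
    if spec.bw_cutoff <= 0:
        raise ValidationError("bw_cutoff must be positive")
    n = vol.values.shape
    if spec.cutoff_units == "cycles_per_mm":
        d = vol.voxel_size_mm
        axes = [np.fft.fftfreq(ni, d=d) for ni in n]
    elif spec.cutoff_units == "cycles_per_pixel":
        axes = [np.fft.fftfreq(ni) for ni in n]
    else:  # fraction_of_nyquist
        axes = [np.fft.fftfreq(ni) / 0.5 for ni in n]
    fz, fy, fx = np.meshgrid(*axes, indexing="ij")
    f = np.sqrt(fz**2 + fy**2 + fx**2)
    h = butterworth_gain(f, spec)
    spec_v = np.fft.fftn(vol.values) * h
    out = np.fft.ifftn(spec_v)
    scale = np.abs(vol.values).max() or 1.0
    if np.abs(out.imag).max() > 1e-10 * scale:
        raise RuntimeError("unexpected imaginary residue in Butterworth output")
    return vol.with_values(np.maximum(out.real, 0.0), role="reconstruction")


def apply_filter(vol: Volume, spec: FilterSpec) -> Volume:
    if spec.kind == "gaussian":
        return gaussian_postfilter(vol, spec)
    return butterworth_postfilter(vol, spec)
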