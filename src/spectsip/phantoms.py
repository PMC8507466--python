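"""Synthetic abdominal activity/attenuation phantoms.

Emulates an In-111 octreotide patient study at desk scale: an ellipsoidal
soft-tissue body with uniform background uptake and a handful of hot
spherical lesions (neuroendocrine-tumour-like contrast). Each phantom is a
pair of co-registered volumes — activity (arbitrary units/voxel) and
attenuation (mm^-1, uniform inside the body, zero outside).

Voxel membership is decided by a voxel-center-inside-surface test, which
makes every count exactly reproducible and cheap to verify by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError, Volume, voxel_center_coords_mm

# ~water linear attenuation at the 245-keV In-111 photopeak
DEFAULT_MU_MM = 0.0127


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid; center and semi-axes in mm (volume-centered frame)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError("ellipsoid semi-axes must be positive")

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        cz, cy, cx = self.center_mm
        az, ay, ax = self.semi_axes_mm
        return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


@dataclass
class Lesion:
    """Hot sphere/ellipsoid; activity is ``activity_ratio`` x background."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    activity_ratio: float

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.radii_mm):
            raise ValidationError("lesion radii must be non-negative")
        if self.activity_ratio < 0:
            raise ValidationError("activity_ratio must be non-negative")

    @classmethod
    def sphere(cls, center_mm, radius_mm: float, activity_ratio: float) -> "Lesion":
        return cls(tuple(center_mm), (radius_mm, radius_mm, radius_mm), activity_ratio)

    def contains(self, z, y, x) -> np.ndarray:
        rz, ry, rx = self.radii_mm
        if min(rz, ry, rx) == 0:
            return np.zeros(np.broadcast(z, y, x).shape, dtype=bool)
        cz, cy, cx = self.center_mm
        return ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    grid_size: int = 64
    voxel_size_mm: float = 4.42
    body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (120.0, 90.0, 110.0))
    )
    background_activity: float = 1.0
    attenuation_mu: float = DEFAULT_MU_MM
    lesions: list[Lesion] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ValidationError("grid_size must be >= 1")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        if self.background_activity < 0:
            raise ValidationError("background_activity must be non-negative")
        if self.attenuation_mu < 0:
            raise ValidationError("attenuation_mu must be non-negative")


def _lesion_contained(lesion: Lesion, body: Ellipsoid) -> bool:
    # Conservative bound: inflate |center offset| by the lesion radius on each
    # axis; if that point satisfies the ellipsoid inequality the lesion fits.
    s = 0.0
    for c_l, r_l, c_b, a_b in zip(
        lesion.center_mm, lesion.radii_mm, body.center_mm, body.semi_axes_mm
    ):
        s += ((abs(c_l - c_b) + r_l) / a_b) ** 2
    return s <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Rasterize a phantom spec into an (activity, attenuation) volume pair.

    Lesion voxels are *set* to ``background_activity * activity_ratio``
    (later lesions overwrite earlier ones where they overlap).
    """
    for lesion in spec.lesions:
        if max(lesion.radii_mm) > 0 and not _lesion_contained(lesion, spec.body):
            raise ValidationError(
                f"lesion at {lesion.center_mm} mm is not fully contained in the body"
            )

    c = voxel_center_coords_mm(spec.grid_size, spec.voxel_size_mm)
    z, y, x = np.meshgrid(c, c, c, indexing="ij")
    body_mask = spec.body.contains(z, y, x)

    activity = np.where(body_mask, spec.background_activity, 0.0)
    for lesion in spec.lesions:
        m = lesion.contains(z, y, x)
        activity[m] = spec.background_activity * lesion.activity_ratio
    attenuation = np.where(body_mask, spec.attenuation_mu, 0.0)

    return (
        Volume(activity, spec.voxel_size_mm, "activity"),
        Volume(attenuation, spec.voxel_size_mm, "attenuation"),
    )


def random_spec(
    base_spec: PhantomSpec,
    rng: np.random.Generator,
    n_lesions_range: tuple[int, int] = (1, 5),
    radius_range_mm: tuple[float, float] = (10.0, 30.0),
    ratio_range: tuple[float, float] = (4.0, 10.0),
    max_tries: int = 1000,
) -> PhantomSpec:
    """Draw a randomized lesion layout on top of ``base_spec``'s body."""
    n_lesions = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
    body = base_spec.body
    a = np.asarray(body.semi_axes_mm)
    lesions: list[Lesion] = []
    for _ in range(n_lesions):
        ratio = float(rng.uniform(*ratio_range))
        for _try in range(max_tries):
            radius = float(rng.uniform(*radius_range_mm))
            # Center sampled in the body ellipsoid shrunk by the lesion's
            # normalized radius; the L2 triangle inequality then guarantees
            # the conservative containment test passes.
            shrink = 1.0 - float(np.sqrt(np.sum((radius / a) ** 2)))
            if shrink <= 0:
                continue  # lesion too large for this body; redraw the radius
            u = rng.normal(size=3)
            u *= rng.uniform() ** (1 / 3) / np.linalg.norm(u)
            center = tuple(np.asarray(body.center_mm) + u * a * shrink)
            cand = Lesion.sphere(center, radius, ratio)
            if _lesion_contained(cand, body):
                lesions.append(cand)
                break
        else:
            raise ValidationError("could not place a lesion inside the body")
    return PhantomSpec(
        grid_size=base_spec.grid_size,
        voxel_size_mm=base_spec.voxel_size_mm,
        body=base_spec.body,
        background_activity=base_spec.background_activity,
        attenuation_mu=base_spec.attenuation_mu,
        lesions=lesions,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int, base_spec: PhantomSpec, seed: int
) -> list[tuple[Volume, Volume]]:
    """Generate ``n`` randomized phantom pairs; reproducible for a fixed seed."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        spec = random_spec(base_spec, rng)
        cohort.append(generate_phantom(spec))
    return cohort


def cohort_specs(n: int, base_spec: PhantomSpec, seed: int) -> list[PhantomSpec]:
    """The specs that :func:`generate_cohort` would rasterize (same draws)."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    return [random_spec(base_spec, rng) for _ in range(n)]
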