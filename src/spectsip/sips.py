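"""Synthetic intermediate projections (SIPs) from a sparse acquisition.

A full orbit of ``n_full`` views (120 by default) is split into the
acquired quarter {1, 5, ..., n_full-3} and three interleaved synthetic sets
{2, 6, ...}, {3, 7, ...}, {4, 8, ...}. The missing 3/4 of the views are
filled in either by circular angular interpolation (the always-available
baseline) or by three small 3D U-nets, one per synthetic set
(:mod:`spectsip.unet`). The sparse set plus the three SIP sets are then
assembled back into a full-orbit projection set for reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ValidationError
from .projector import ProjectionSet


@dataclass
class SIPIndexPlan:
    """Partition of 1..n_full into acquired + three synthetic index sets."""

    n_full: int
    acquired: np.ndarray
    sip_sets: tuple[np.ndarray, np.ndarray, np.ndarray]

    def all_sip_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(self.sip_sets))


def sip_index_plan(n_full: int = 120) -> SIPIndexPlan:
    """The interleaved acquisition plan for an orbit of ``n_full`` views."""
    if n_full < 4 or n_full % 4 != 0:
        raise ValidationError("n_full must be a positive multiple of 4")
    acquired = np.arange(1, n_full + 1, 4)
    sip_sets = tuple(np.arange(1 + k, n_full + 1, 4) for k in (1, 2, 3))
    return SIPIndexPlan(n_full=n_full, acquired=acquired, sip_sets=sip_sets)


def normalize(sparse: ProjectionSet) -> tuple[ProjectionSet, float]:
    """Scale the whole set by its global maximum; returns (scaled set, max)."""
    scale = float(sparse.counts.max()) if len(sparse) else 0.0
    if scale <= 0:
        raise ValidationError("cannot normalize an all-zero projection set")
    return sparse.replace_counts(sparse.counts / scale), scale


def pack_input(sparse: ProjectionSet, angle_slots: int = 128) -> np.ndarray:
    """Pack a normalized sparse set into a (side, side, angle_slots) tensor.

    Each sparse projection is replicated into the 4 consecutive angle slots
    it anchors (slots 1..n_full in acquisition order); the remaining
    ``angle_slots - n_full`` slots wrap circularly to the first slots, so a
    120-view orbit fills a 128-deep tensor seamlessly.
    """
    n_sparse = len(sparse)
    n_full = 4 * n_sparse
    plan = sip_index_plan(n_full)
    if not np.array_equal(sparse.indices, plan.acquired):
        raise ValidationError(
            f"sparse set must hold the {n_full // 4} acquired views {plan.acquired[:3]}..."
        )
    if angle_slots < n_full:
        raise ValidationError(f"angle_slots {angle_slots} < n_full {n_full}")
    side = sparse.counts.shape[1]
    cube = np.empty((side, side, angle_slots))
    full = np.repeat(sparse.counts, 4, axis=0)  # slot k holds projection floor(k/4)
    cube[:, :, :n_full] = full.transpose(1, 2, 0)
    if angle_slots > n_full:
        cube[:, :, n_full:] = cube[:, :, : angle_slots - n_full]
    return cube


def crop_output(
    output: np.ndarray,
    plan: SIPIndexPlan,
    set_id: int,
    template: ProjectionSet,
    scale: float,
) -> tuple[ProjectionSet, int]:
    """Extract one synthetic set from a network output tensor.

    Slot k (1-based, k <= n_full) corresponds to projection index k. Values
    are denormalized by ``scale`` and clipped at zero; the number of clipped
    voxels is returned as a QC counter. ``template`` supplies pixel size,
    count scale and the orbit length for angle computation.
    """
    if set_id not in (1, 2, 3):
        raise ValidationError("set_id must be 1, 2 or 3")
    if output.shape[2] < plan.n_full:
        raise ValidationError("output tensor has fewer slots than the orbit")
    idx = plan.sip_sets[set_id - 1]
    stack = output[:, :, idx - 1].transpose(2, 0, 1) * scale
    n_clipped = int((stack < 0).sum())
    stack = np.maximum(stack, 0.0)
    step = 360.0 / plan.n_full if plan.n_full else 0.0
    angles = (idx - 1) * step
    return (
        ProjectionSet(
            counts=stack,
            indices=idx,
            angles_deg=angles,
            pixel_size_mm=template.pixel_size_mm,
            count_scale=template.count_scale,
        ),
        n_clipped,
    )


def interpolate_sips(
    sparse: ProjectionSet, plan: SIPIndexPlan
) -> tuple[ProjectionSet, ProjectionSet, ProjectionSet]:
    """Circular linear angular interpolation between flanking acquired views.

    The synthetic view at index k is a convex combination of its two
    neighbouring acquired views with weights ``(4 - d)/4`` and ``d/4`` where
    ``d = k - preceding acquired index``; past the end of the orbit the
    first acquired view wraps around.
    """
    if not np.array_equal(sparse.indices, plan.acquired):
        raise ValidationError("sparse set indices do not match the plan's acquired set")
    n_sparse = len(sparse)
    step = 360.0 / plan.n_full
    out = []
    for sip_idx in plan.sip_sets:
        delta = sip_idx - (sip_idx - 1) // 4 * 4 - 1  # k - preceding acquired index
        prev = (sip_idx - 1) // 4  # position of preceding acquired view
        nxt = (prev + 1) % n_sparse
        w_next = delta / 4.0
        counts = (1.0 - w_next)[:, None, None] * sparse.counts[prev] + w_next[
            :, None, None
        ] * sparse.counts[nxt]
        out.append(
            ProjectionSet(
                counts=counts,
                indices=sip_idx,
                angles_deg=(sip_idx - 1) * step,
                pixel_size_mm=sparse.pixel_size_mm,
                count_scale=sparse.count_scale,
            )
        )
    return tuple(out)


def assemble_full_set(
    sparse: ProjectionSet,
    sips: tuple[ProjectionSet, ProjectionSet, ProjectionSet],
    plan: SIPIndexPlan,
) -> ProjectionSet:
    """Merge acquired and synthetic views into one angle-ordered full orbit.

    Acquired projections are carried over bit-identically; the index sets
    must tile 1..n_full exactly.
    """
    pieces = [sparse, *sips]
    all_idx = np.concatenate([p.indices for p in pieces])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValidationError("overlapping projection indices")
    if not np.array_equal(np.sort(all_idx), np.arange(1, plan.n_full + 1)):
        raise ValidationError("index sets do not tile the full orbit")
    side = sparse.counts.shape[1]
    counts = np.empty((plan.n_full, side, side))
    angles = np.empty(plan.n_full)
    for p in pieces:
        counts[p.indices - 1] = p.counts
        angles[p.indices - 1] = p.angles_deg
    return ProjectionSet(
        counts=counts,
        indices=np.arange(1, plan.n_full + 1),
        angles_deg=angles,
        pixel_size_mm=sparse.pixel_size_mm,
        count_scale=sparse.count_scale,
    )
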