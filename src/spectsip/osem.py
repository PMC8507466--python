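"""Ordered-subset expectation-maximization reconstruction.

Standard multiplicative OSEM over the matched forward/adjoint pair of
:mod:`spectsip.projector`:

    x  <-  (x / s_b) * A_b^T( y_b / max(A_b x, eps) )

cycling the angular subsets b in natural order for a fixed number of full
passes. ``s_b = A_b^T 1`` is the subset sensitivity; voxels with zero
sensitivity stay zero. With a single subset this is ML-EM, which preserves
total counts (sum_j s_j x_j = sum_i y_i) after every full iteration and has
the true activity as a fixed point on noiseless data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ValidationError, Volume
from .projector import ForwardOperator, ProjectionSet, SystemModel, _positions_for


@dataclass
class ReconConfig:
    n_subsets: int = 6
    n_iterations: int = 10
    init: str = "uniform"  # {"uniform", "backprojection"}
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValidationError("n_subsets must be >= 1")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.init not in ("uniform", "backprojection"):
            raise ValidationError(f"unknown init {self.init!r}")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")


def partition_subsets(indices: np.ndarray, n_subsets: int) -> list[np.ndarray]:
    """Stride the angle-ordered index list into ``n_subsets`` interleaved subsets.

    Subset s (1-based) takes every ``n_subsets``-th entry starting at
    position s, so each subset spans the full angular range with maximal
    intra-subset spacing. Subsets are disjoint, equal-sized and cover the
    input.
    """
    indices = np.asarray(indices)
    if n_subsets < 1:
        raise ValidationError("n_subsets must be >= 1")
    if len(indices) % n_subsets != 0:
        raise ValidationError(
            f"{len(indices)} projections not divisible into {n_subsets} subsets"
        )
    return [indices[s::n_subsets] for s in range(n_subsets)]


def osem_reconstruct(
    proj: ProjectionSet,
    attenuation: Volume,
    model: SystemModel,
    config: ReconConfig | None = None,
    initial: Volume | None = None,
    operator: ForwardOperator | None = None,
) -> Volume:
    """Reconstruct an activity volume from a projection set.

    ``initial`` overrides the configured initialization (useful for
    fixed-point checks); otherwise a uniform positive volume inside the
    attenuation support (or everywhere, if the map is empty) is used.
    ``operator`` lets callers reuse a prebuilt forward operator when
    reconstructing several sets against the same attenuation map.
    """
    config = config or ReconConfig()
    if np.any(proj.counts < 0):
        raise ValidationError("negative projection counts")

    if proj.counts.sum() == 0:
        warnings.warn("all-zero projection set: returning a zero volume")
        return Volume(
            np.zeros(attenuation.shape), attenuation.voxel_size_mm, "reconstruction"
        )

    op = operator if operator is not None else ForwardOperator(attenuation, model)
    positions = _positions_for(proj, model.geometry)
    # subsets are positions *within the set* (rows of proj.counts)
    local = np.arange(len(proj))
    subsets = partition_subsets(local, config.n_subsets)

    sens = [op.backproject_positions(np.ones_like(proj.counts[s]), positions[s])
            for s in subsets]

    if initial is not None:
        x = initial.values.copy()
    elif config.init == "backprojection":
        x = op.backproject_positions(proj.counts, positions)
    else:
        support = attenuation.values > 0
        if not support.any():
            support = np.ones(op.shape, dtype=bool)
        x = np.where(support, 1.0, 0.0)

    eps = config.epsilon
    for _ in range(config.n_iterations):
        for s, s_map in zip(subsets, sens):
            f = op.project_positions(x, positions[s])
            y = proj.counts[s]
            # y/f wherever the model sees counts; the epsilon guard only
            # handles an exactly-zero denominator (zero model & zero count
            # contribute zero), and a ceiling keeps the arithmetic finite.
            ratio = np.where(f > 0, y / np.where(f > 0, f, 1.0),
                             np.where(y > 0, y / eps, 0.0))
            ratio = np.minimum(ratio, 1e30)
            upd = op.backproject_positions(ratio, positions[s])
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(s_map > 0, x * upd / np.maximum(s_map, eps), 0.0)
            x = np.maximum(x, 0.0)

    return Volume(x, attenuation.voxel_size_mm, "reconstruction")


def poisson_loglik(
    x: np.ndarray, proj: ProjectionSet, op: ForwardOperator, eps: float = 1e-12
) -> float:
    """Poisson log-likelihood (up to the y! constant) of activity ``x``."""
    positions = proj.indices - 1
    f = op.project_positions(x, np.asarray(positions))
    y = proj.counts
    return float(np.sum(np.where(y > 0, y * np.log(np.maximum(f, eps)), 0.0) - f))
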