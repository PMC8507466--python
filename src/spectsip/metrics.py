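"""Quantitative image-quality metrics and paired statistics.

Three reference-based metrics for volumes or 2D projections:

* RMSE — root of the mean squared voxelwise difference between an assessed
  image IM and a reference RI;
* PSNR — ``20 log10(MAX / RMSE)`` in dB, with MAX taken from the reference
  image by default (switchable to the assessed image);
* SSIM — mean of the local structural-similarity index

      (2 mu_IM mu_RI + c1)(2 cov + c2)
      --------------------------------------------
      (mu_IM^2 + mu_RI^2 + c1)(var_IM + var_RI + c2)

  over all fully-inside sliding windows (default 3x3x3, stride 1), with
  plain (unweighted, population) window statistics and stabilizers
  ``c1 = (K1 L)^2``, ``c2 = (K2 L)^2``; ``L`` defaults to the dynamic range
  of the reference.

Paired comparisons between arms use the two-sided paired Student's t-test
with Holm (default) or Bonferroni multiple-testing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DegenerateDataError, ValidationError


@dataclass
class MetricsConfig:
    ssim_kernel: int = 3
    K1: float = 0.01
    K2: float = 0.03
    L_policy: str = "reference_range"  # {reference_range, reference_max, explicit}
    L_explicit: float | None = None
    psnr_max_policy: str = "reference_max"  # {reference_max, assessed_max}

    def __post_init__(self) -> None:
        if self.ssim_kernel < 1 or self.ssim_kernel % 2 == 0:
            raise ValidationError("ssim_kernel must be odd and >= 1")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValidationError("K1 and K2 must be positive")
        if self.L_policy not in ("reference_range", "reference_max", "explicit"):
            raise ValidationError(f"unknown L_policy {self.L_policy!r}")
        if self.L_policy == "explicit" and (
            self.L_explicit is None or self.L_explicit <= 0
        ):
            raise ValidationError("explicit L must be positive")
        if self.psnr_max_policy not in ("reference_max", "assessed_max"):
            raise ValidationError(f"unknown psnr_max_policy {self.psnr_max_policy!r}")


def _as_arrays(im, ref) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(getattr(im, "values", im), dtype=np.float64)
    b = np.asarray(getattr(ref, "values", ref), dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(im, ref) -> float:
    """Root-mean-square voxelwise difference."""
    a, b = _as_arrays(im, ref)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(im, ref, config: MetricsConfig | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf (flagged, not raised) if RMSE is 0."""
    config = config or MetricsConfig()
    a, b = _as_arrays(im, ref)
    r = rmse(a, b)
    mx = float(b.max() if config.psnr_max_policy == "reference_max" else a.max())
    if r == 0:
        return float("inf")
    if mx <= 0:
        raise ValidationError("PSNR undefined: non-positive MAX")
    return float(20.0 * np.log10(mx / r))


def _dynamic_range(a: np.ndarray, b: np.ndarray, config: MetricsConfig) -> float:
    if config.L_policy == "explicit":
        return float(config.L_explicit)
    if config.L_policy == "reference_max":
        L = float(b.max())
    else:
        L = float(b.max() - b.min())
    if L <= 0:
        raise ValidationError("SSIM dynamic range L is non-positive")
    return L


def ssim(im, ref, config: MetricsConfig | None = None) -> float:
    """Mean local SSIM over all fully-inside windows (plain window statistics)."""
    config = config or MetricsConfig()
    a, b = _as_arrays(im, ref)
    k = config.ssim_kernel
    if any(s < k for s in a.shape):
        raise ValidationError(f"image shape {a.shape} smaller than {k}-window")
    L = _dynamic_range(a, b, config)
    c1 = (config.K1 * L) ** 2
    c2 = (config.K2 * L) ** 2

    win = (k,) * a.ndim
    axes = tuple(range(-a.ndim, 0))
    mu_a = sliding_window_view(a, win).mean(axis=axes)
    mu_b = sliding_window_view(b, win).mean(axis=axes)
    m_aa = sliding_window_view(a * a, win).mean(axis=axes)
    m_bb = sliding_window_view(b * b, win).mean(axis=axes)
    m_ab = sliding_window_view(a * b, win).mean(axis=axes)
    var_a = m_aa - mu_a**2
    var_b = m_bb - mu_b**2
    cov = m_ab - mu_a * mu_b

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired Student's t-test on the differences ``b - a``.

    Returns (t, p) with n-1 degrees of freedom; a positive t means b > a on
    average.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1D of equal length")
    if len(a) < 3:
        raise ValidationError("paired t-test needs at least 3 pairs")
    d = b - a
    if np.allclose(d.std(ddof=1), 0):
        raise DegenerateDataError("zero-variance paired differences")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment (Holm step-down by default, or Bonferroni)."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p-values must be a non-empty 1D list")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


@dataclass
class MetricsReport:
    """Per-subject per-arm metrics plus paired-test summaries.

    ``per_subject`` is a tidy table (subject, arm, rmse, psnr_db, ssim);
    ``tests`` one row per (family, metric, comparison) with raw and adjusted
    p-values. Built by :func:`spectsip.pipeline.run_experiment`.
    """

    per_subject: pd.DataFrame
    tests: pd.DataFrame
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return (
            self.per_subject.groupby("arm")[["rmse", "psnr_db", "ssim"]]
            .agg(["mean", "std"])
            .sort_index()
        )

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path, index=False)

    def to_json_summary(self) -> dict:
        out = {"arms": {}, "tests": self.tests.to_dict(orient="records")}
        for arm, g in self.per_subject.groupby("arm"):
            out["arms"][arm] = {
                m: {"mean": float(g[m].mean()), "sd": float(g[m].std(ddof=1))}
                for m in ("rmse", "psnr_db", "ssim")
            }
        return out
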