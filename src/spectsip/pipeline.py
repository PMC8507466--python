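"""End-to-end five-arm comparison experiment on a synthetic cohort.

For every cohort member the pipeline simulates a full noisy acquisition,
derives the sparse acquisition and the synthetic intermediate projections,
reconstructs every arm with identical OSEM settings, post-filters the
sparse arm, and scores each arm against the full-acquisition reconstruction:

* ``120P``       — reconstruction of all views (the reference arm);
* ``30P``        — reconstruction of every fourth view;
* ``30-120SIP``  — reconstruction of the 30 acquired + 90 synthetic views;
* ``30GF``       — 30P post-filtered with a 4-mm-SD Gaussian;
* ``30BW``       — 30P post-filtered with an order-2 Butterworth.

Paired t-tests compare arms per metric in two families: every sparse-based
arm against 30-120SIP, and 30P against its post-filtered versions; p-values
are Holm-adjusted within each (family, metric) group.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .core import ValidationError, Volume
from .filters import FilterSpec, apply_filter
from .metrics import MetricsConfig, MetricsReport, adjust_pvalues, paired_ttest
from .metrics import rmse as _rmse, psnr as _psnr, ssim as _ssim
from .osem import ReconConfig, osem_reconstruct
from .phantoms import PhantomSpec, cohort_specs, generate_phantom
from .projector import (
    AcquisitionGeometry,
    ForwardOperator,
    SystemModel,
    add_poisson_noise,
    forward_project,
    subsample_sparse,
)
from .sips import assemble_full_set, interpolate_sips, sip_index_plan
from .unet import NetworkConfig, TrainingConfig

ARMS = ("120P", "30P", "30-120SIP", "30GF", "30BW")
COMPARISON_ARMS = ("30P", "30-120SIP", "30GF", "30BW")


@dataclass
class ExperimentConfig:
    n_subjects: int = 10
    base_phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort_seed: int = 1234
    noise_seed: int = 5678
    count_scale: float = 1e5
    noise: bool = True  # False -> ideal (noiseless) acquisitions
    system: SystemModel = field(default_factory=lambda: SystemModel(
        geometry=AcquisitionGeometry(n_angles=120, matrix_size=64)
    ))
    recon: ReconConfig = field(default_factory=ReconConfig)
    sip_method: str = "interp"  # {"interp", "unet"}
    network: NetworkConfig | None = None
    training: TrainingConfig | None = None
    n_training_pairs: int = 20
    gaussian_filter: FilterSpec = field(default_factory=lambda: FilterSpec(kind="gaussian"))
    butterworth_filter: FilterSpec = field(
        default_factory=lambda: FilterSpec(kind="butterworth")
    )
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    out_dir: str | None = None
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.sip_method not in ("interp", "unet"):
            raise ValidationError(f"unknown sip_method {self.sip_method!r}")
        geo = self.system.geometry
        if geo.matrix_size != self.base_phantom.grid_size:
            raise ValidationError("matrix_size must equal the phantom grid size")
        if abs(geo.pixel_size_mm - self.base_phantom.voxel_size_mm) > 1e-9:
            raise ValidationError("pixel size must equal the phantom voxel size")


def simulate_subject(
    spec: PhantomSpec, config: ExperimentConfig, noise_seed: int
):
    """One subject's phantoms and its full noisy acquisition."""
    activity, attenuation = generate_phantom(spec)
    clean = forward_project(activity, attenuation, config.system)
    clean = dataclasses.replace(clean, count_scale=config.count_scale)
    if not config.noise:
        return activity, attenuation, clean
    noisy = add_poisson_noise(clean, noise_seed)
    return activity, attenuation, noisy


def _generate_sips(sparse, plan, config: ExperimentConfig, models=None):
    if config.sip_method == "interp":
        return interpolate_sips(sparse, plan)
    from .sips import crop_output, normalize, pack_input

    norm, scale = normalize(sparse)
    cube = pack_input(norm, config.network.angle_slots)
    out = []
    for set_id, model in zip((1, 2, 3), models):
        pred = model.forward(cube)
        sip_set, _ = crop_output(pred, plan, set_id, sparse, scale)
        out.append(sip_set)
    return tuple(out)


def train_sip_models(config: ExperimentConfig, seed: int | None = None):
    """Train the three per-set networks on a synthetic training cohort."""
    from .sips import normalize, pack_input
    from .unet import build_network, train_sip_network

    if config.network is None or config.training is None:
        raise ValidationError("unet sip_method requires network and training configs")
    seed = config.cohort_seed + 99 if seed is None else seed
    specs = cohort_specs(config.n_training_pairs, config.base_phantom, seed)
    plan = sip_index_plan(config.system.geometry.n_angles)
    datasets: dict[int, list] = {1: [], 2: [], 3: []}
    for i, spec in enumerate(specs):
        _, _, noisy = simulate_subject(spec, config, seed + 1000 + i)
        sparse = subsample_sparse(noisy)
        norm, scale = normalize(sparse)
        cube = pack_input(norm, config.network.angle_slots)
        for set_id in (1, 2, 3):
            idx = plan.sip_sets[set_id - 1]
            target = noisy.counts[idx - 1] / scale
            datasets[set_id].append((cube, target, idx - 1))
    models, histories = [], []
    for set_id in (1, 2, 3):
        model = build_network(config.network)
        model, hist = train_sip_network(model, datasets[set_id], config.training)
        models.append(model)
        histories.append(hist)
    return models, histories


def _reconstruct(proj, attenuation, config: ExperimentConfig, operator=None) -> Volume:
    return osem_reconstruct(
        proj, attenuation, config.system, config.recon, operator=operator
    )


def run_experiment(config: ExperimentConfig, models=None) -> MetricsReport:
    """Run the full five-arm comparison; returns the metrics report.

    All randomness derives from ``config.cohort_seed``/``config.noise_seed``,
    so a re-run with the same config reproduces the report bit-for-bit. If
    ``config.out_dir`` is set, per-subject CSV, JSON summary and a
    provenance record are written there (volumes/projections too when
    ``save_volumes``).
    """
    specs = cohort_specs(config.n_subjects, config.base_phantom, config.cohort_seed)
    plan = sip_index_plan(config.system.geometry.n_angles)
    if config.sip_method == "unet" and models is None:
        models, _ = train_sip_models(config)

    out_dir = sio.ensure_dir(config.out_dir) if config.out_dir else None
    mcfg = config.metrics
    rows = []
    for i, spec in enumerate(specs):
        activity, attenuation, noisy = simulate_subject(
            spec, config, config.noise_seed + i
        )
        sparse = subsample_sparse(noisy)
        sips = _generate_sips(sparse, plan, config, models)
        full_sip = assemble_full_set(sparse, sips, plan)

        op = ForwardOperator(attenuation, config.system)
        recons = {
            "120P": _reconstruct(noisy, attenuation, config, op),
            "30P": _reconstruct(sparse, attenuation, config, op),
            "30-120SIP": _reconstruct(full_sip, attenuation, config, op),
        }
        recons["30GF"] = apply_filter(recons["30P"], config.gaussian_filter)
        recons["30BW"] = apply_filter(recons["30P"], config.butterworth_filter)

        ref = recons["120P"]
        for arm in COMPARISON_ARMS:
            rows.append(
                {
                    "subject": i,
                    "arm": arm,
                    "rmse": _rmse(recons[arm], ref),
                    "psnr_db": _psnr(recons[arm], ref, mcfg),
                    "ssim": _ssim(recons[arm], ref, mcfg),
                }
            )
        # projection-domain quality of the SIPs vs the held-out acquired views
        sip_idx = plan.all_sip_indices()
        sip_stack = full_sip.counts[sip_idx - 1]
        true_stack = noisy.counts[sip_idx - 1]
        rows.append(
            {
                "subject": i,
                "arm": "SIPs",
                "rmse": float(
                    np.mean([_rmse(s, t) for s, t in zip(sip_stack, true_stack)])
                ),
                "psnr_db": float(
                    np.mean([_psnr(s, t, mcfg) for s, t in zip(sip_stack, true_stack)])
                ),
                "ssim": float(
                    np.mean([_ssim(s, t, mcfg) for s, t in zip(sip_stack, true_stack)])
                ),
            }
        )
        if out_dir is not None and config.save_volumes:
            sdir = sio.ensure_dir(out_dir / f"subject_{i:03d}")
            sio.save_projections(sdir / "projections_120.h5", noisy)
            sio.save_projections(sdir / "projections_30.h5", sparse)
            sio.save_projections(sdir / "projections_30_120sip.h5", full_sip)
            for arm, vol in recons.items():
                sio.save_volume(sdir / f"recon_{arm}.nii.gz", vol)

    per_subject = pd.DataFrame(rows)
    tests = _paired_tests(per_subject)
    report = MetricsReport(per_subject=per_subject, tests=tests,
                           config=_config_provenance(config))
    if out_dir is not None:
        report.to_csv(out_dir / "metrics_per_subject.csv")
        with open(out_dir / "summary.json", "w") as f:
            json.dump(report.to_json_summary(), f, indent=2)
        with open(out_dir / "provenance.json", "w") as f:
            json.dump(report.config, f, indent=2, default=str)
    return report


def _paired_tests(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Two comparison families, Holm-adjusted within each (family, metric)."""
    cols = ["family", "metric", "comparison", "t", "p_raw", "p_adj"]
    if per_subject.subject.nunique() < 3:
        return pd.DataFrame(columns=cols)  # too few pairs for a t-test
    wide = {
        arm: per_subject[per_subject.arm == arm].sort_values("subject")
        for arm in COMPARISON_ARMS
    }
    families = {
        "vs_SIP": [("30P", "30-120SIP"), ("30GF", "30-120SIP"), ("30BW", "30-120SIP")],
        "filtering": [("30P", "30GF"), ("30P", "30BW")],
    }
    rows = []
    for family, pairs in families.items():
        for metric in ("rmse", "psnr_db", "ssim"):
            recs = []
            for a, b in pairs:
                t, p = paired_ttest(
                    wide[a][metric].to_numpy(), wide[b][metric].to_numpy()
                )
                recs.append({"family": family, "metric": metric,
                             "comparison": f"{a} vs {b}", "t": t, "p_raw": p})
            adj = adjust_pvalues([r["p_raw"] for r in recs])
            for r, pa in zip(recs, adj):
                r["p_adj"] = float(pa)
            rows.extend(recs)
    return pd.DataFrame(rows)


def _config_provenance(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# config file support
# ---------------------------------------------------------------------------


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a plain (YAML-loaded) dictionary."""
    from .phantoms import Ellipsoid, Lesion

    kwargs: dict = {}
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        if "body" in ph:
            ph["body"] = Ellipsoid(tuple(ph["body"]["center_mm"]),
                                   tuple(ph["body"]["semi_axes_mm"]))
        if "lesions" in ph:
            ph["lesions"] = [
                Lesion(tuple(l["center_mm"]), tuple(l["radii_mm"]), l["activity_ratio"])
                for l in ph["lesions"]
            ]
        kwargs["base_phantom"] = PhantomSpec(**ph)
    if "geometry" in raw or "system" in raw:
        geo = AcquisitionGeometry(**raw.get("geometry", {}))
        kwargs["system"] = SystemModel(geometry=geo, **raw.get("system", {}))
    if "recon" in raw:
        kwargs["recon"] = ReconConfig(**raw["recon"])
    if "network" in raw:
        kwargs["network"] = NetworkConfig(**raw["network"])
    if "training" in raw:
        kwargs["training"] = TrainingConfig(**raw["training"])
    if "gaussian_filter" in raw:
        kwargs["gaussian_filter"] = FilterSpec(kind="gaussian", **raw["gaussian_filter"])
    if "butterworth_filter" in raw:
        kwargs["butterworth_filter"] = FilterSpec(
            kind="butterworth", **raw["butterworth_filter"]
        )
    if "metrics" in raw:
        kwargs["metrics"] = MetricsConfig(**raw["metrics"])
    for key in (
        "n_subjects", "cohort_seed", "noise_seed", "count_scale", "sip_method",
        "n_training_pairs", "out_dir", "save_volumes",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return ExperimentConfig(**kwargs)


def load_config(path) -> ExperimentConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return config_from_dict(raw)
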