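# spectsip

Sparse-view SPECT with synthetic intermediate projections (SIPs), at desk
scale.

Long acquisition times are a standing problem in single-photon emission
computed tomography: a low-noise abdominal ¹¹¹In-octreotide study needs
about 30 minutes for 120 projections. Acquiring only every fourth
projection would cut that 4-fold, at the cost of noisier, artifact-prone
reconstructions. One proposed remedy is to *synthesize* the 90 missing
intermediate projections from the 30 acquired ones and feed all 120 into
the reconstruction. `spectsip` implements the full comparison pipeline for
studying that idea on synthetic data: digital phantom cohorts, an analytic
attenuation + collimator-response projection simulator with Poisson noise,
ordered-subset EM reconstruction, two SIP generators (circular angular
interpolation, and a small 3D U-net trained per interleaved index set),
Gaussian/Butterworth post-filter comparison arms, and quantitative
evaluation with paired statistics.

## The core computation

Reconstruction is multiplicative OSEM over a matched projector/adjoint
pair (6 subsets, 10 iterations by default):

    x  ←  (x / s_b) · A_bᵀ( y_b / A_b x ),      s_b = A_bᵀ 1

where `A` models in-plane rotation, attenuation `exp(-∫ μ dl)`, and a
depth-dependent Gaussian collimator-detector response σ(d) = σ₀ + slope·d.
Five arms are reconstructed per subject — all 120 views (`120P`, the
reference), the sparse 30 (`30P`), the 30 acquired + 90 synthetic views
(`30-120SIP`), and `30P` post-filtered with a 4-mm-SD Gaussian (`30GF`) or
an order-2 Butterworth, cutoff 0.036 cycles/mm (`30BW`). Each arm is
scored against `120P` with

* RMSE — root mean squared voxelwise difference,
* PSNR = 20·log₁₀(MAX / RMSE) in dB,
* SSIM — mean of (2μ_IM μ_RI + c₁)(2σ_IMRI + c₂) / ((μ_IM² + μ_RI² + c₁)(σ_IM² + σ_RI² + c₂))
  over sliding 3×3×3 windows, c₁ = (0.01 L)², c₂ = (0.03 L)²,

and arms are compared with two-sided paired t-tests, Holm-adjusted.

## Worked example

The default experiment (10 synthetic subjects, 64³ grids with 4.42-mm
voxels, 120 views over 360°, ~10⁵ counts/projection, interpolation SIPs)
runs in a few minutes on one CPU core:

```python
from spectsip.pipeline import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig())
print(report.summary())
print(report.tests[report.tests.family == "vs_SIP"].to_string(index=False))
```

prints (abridged):

```
               rmse              psnr_db                ssim
               mean       std       mean       std      mean       std
arm
30-120SIP  0.111187  0.009299  52.160947  2.384509  0.998072  0.000976
30BW       0.256197  0.008985  44.889248  2.603800  0.978158  0.008027
30GF       0.289156  0.009073  43.837134  2.416322  0.974207  0.009098
30P        0.114148  0.004056  51.911418  2.376567  0.997609  0.001227
SIPs       6.215803  0.013196  27.086242  1.346266  0.655296  0.034066

   family  metric        comparison          t        p_raw        p_adj
   vs_SIP    rmse  30P vs 30-120SIP  -1.137929 2.845353e-01 2.845353e-01
   vs_SIP    rmse 30GF vs 30-120SIP -47.083764 4.403843e-12 1.321153e-11
   vs_SIP    rmse 30BW vs 30-120SIP -31.957475 1.412959e-10 2.825918e-10
   vs_SIP    ssim  30P vs 30-120SIP   5.640576 3.173887e-04 3.173887e-04
   vs_SIP    ssim 30GF vs 30-120SIP   9.268752 6.707300e-06 2.012190e-05
   vs_SIP    ssim 30BW vs 30-120SIP   8.907627 9.289183e-06 2.012190e-05
```

Reading it: the SIP-augmented arm tracks the full-acquisition reference
more closely than both post-filtered sparse arms on every metric
(p ≪ 0.001), and is significantly better than the raw sparse arm in SSIM
(0.99807 vs 0.99761, Holm p = 3.2e-4). Its RMSE is lower than `30P`'s in
most subjects but the paired contrast is not significant at these
conditions — with an exactly matched system model a 30-view OSEM
reconstruction suffers almost no angular-undersampling penalty, so the
RMSE comparison comes down to interpolation bias versus noise smoothing
(see `docs/methods.md`). The `SIPs` row scores the synthetic projections
themselves against the held-out acquired views in the projection domain.

The same experiment is available from the shell:

```
spectsip run-all --config examples/experiment.yaml --seed 7 --out results/
```

with subcommands `simulate`, `train`, `sip`, `reconstruct`, `evaluate` for
the individual stages (HDF5 projections, NIfTI volumes, CSV/JSON reports).

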