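# Methods

`spectsip` studies a practical question in nuclear-medicine imaging: if a
SPECT acquisition is cut from 120 gantry views to 30 (a 4-fold reduction in
scan time), how much image quality is lost, and how much of it can be
recovered by filling the 90 unacquired angles with *synthetic intermediate
projections* (SIPs) before reconstruction? The package provides every stage
of that experiment — digital phantoms, an analytic projection simulator, an
ordered-subset EM reconstructor, two SIP generators, post-filters, and the
quantitative evaluation — as seeded, testable components.

## Experimental design

Five reconstruction arms are compared per synthetic subject:

| arm | data |
|---|---|
| `120P` | all 120 noisy views (the reference arm) |
| `30P` | every fourth view (indices 1, 5, ..., 117) |
| `30-120SIP` | the 30 acquired views plus 90 SIPs at indices {2,6,...,118}, {3,7,...,119}, {4,8,...,120} |
| `30GF` | the `30P` reconstruction post-smoothed with a Gaussian, SD 4 mm |
| `30BW` | the `30P` reconstruction post-filtered with an order-2 Butterworth, cutoff 0.036 cycles/mm |

All arms are reconstructed with identical OSEM settings (6 subsets, 10
iterations). Each non-reference arm is scored against `120P` with RMSE,
PSNR and a 3×3×3-kernel SSIM, and arms are compared with two-sided paired
t-tests, Holm-adjusted within two families: (a) each sparse-based arm vs
`30-120SIP`, and (b) `30P` vs its post-filtered versions. SIP quality is
additionally scored in the projection domain against the held-out acquired
views.

## Phantoms

A subject is an ellipsoidal soft-tissue body (default semi-axes 120 × 90 ×
110 mm) with uniform background uptake and 1–5 hot spherical lesions
(radii 10–30 mm, uptake ratios 4–10 over background), emulating the
contrast of somatostatin-receptor-positive neuroendocrine tumours. The
attenuation map is uniform water-like inside the body (μ = 0.0127 mm⁻¹ at
the 245-keV photopeak) and zero outside. Voxel membership uses a
voxel-center-inside-surface test, so every voxel count is exactly
reproducible and brute-force verifiable. Lesion placement samples centers
inside the body ellipsoid shrunk by the lesion's normalized radius, which
guarantees containment by the triangle inequality.

What the generator does *not* emulate: anatomical texture, organ-specific
uptake (liver/spleen/kidneys), CT-derived heterogeneous attenuation, or
patient motion. Passing tests therefore demonstrate the pipeline's internal
consistency and the direction of sparse-view effects on piecewise-constant
objects, not clinical performance.

## Projection simulator and system model

The forward operator is a rotation-based parallel-hole model. Per view:

1. the volume is resampled into the detector frame by an in-plane rotation
   implemented as bilinear *splatting* (each source voxel deposits its full
   value with weights summing to 1), so counts are conserved exactly;
2. each emission plane is attenuated by `exp(-∫μ dl)` toward the detector,
   accumulated plane-by-plane with a half-voxel offset at the emitter;
3. each plane is blurred with a depth-dependent Gaussian collimator-detector
   response, σ(d) = σ₀ + slope·d (defaults σ₀ = 3 mm, slope = 0.04, a
   medium-energy parallel-hole ballpark), applied via FFT with a spatially
   sampled, circularly wrapped kernel. Sampling the kernel in the *spatial*
   domain keeps it non-negative for sub-voxel sigmas (a frequency-sampled
   Gaussian truncates at Nyquist and rings), its unit sum makes the DC gain
   exactly 1, and its symmetry makes the blur self-adjoint;
4. planes are summed along depth; an optional effective scatter term adds
   `scatter_fraction ×` a broad-kernel (FWHM 3× PSF) copy of the projection.

Every stage is linear with an exactly matched adjoint, verified by the
inner-product identity and against an explicit dense matrix transpose on
small instances. Poisson noise is applied after scaling pixel means so the
average projection total equals `count_scale` (default 10⁵ counts per
projection, a plausible 30-s-frame total for a 111-In somatostatin-analogue
study one day post injection).

Known approximations: circular FFT wrap-around (negligible for
interior-supported objects), no septal penetration, no energy response, and
the reconstructor shares the simulator's system model — an idealization a
Monte-Carlo-based reconstructor approaches but never reaches. The last
point matters for interpretation; see "Findings" below.

## Reconstruction

Standard multiplicative OSEM, `x ← (x/s_b)·A_bᵀ(y_b / A_b x)`, cycling
stride-partitioned angular subsets in natural order (subset s takes every
n-th view of the ordered list, maximizing intra-subset angular spread).
The denominator is guarded only when the model value is exactly zero
(`ε = 1e-12`; zero model and zero count contribute zero), which preserves
the ML-EM identities to floating precision: total-count preservation each
full 1-subset iteration, fixed point at the truth on noiseless data, and
invariance to rescaling the initial estimate. Initialization is uniform
inside the attenuation support. No inter-iteration filtering or relaxation.

## SIP generation

Two generators fill the 90 unacquired angles:

* **Angular interpolation** (always available): the SIP at index k is the
  convex combination of its flanking acquired views with weights
  (4−δ)/4 and δ/4, δ = k − preceding acquired index, wrapping circularly
  past index 120. Exact for projections that vary linearly with view index.
* **3D U-net** (one independent network per synthetic index set): the 30
  normalized views are replicated 4× along the angle axis and circularly
  padded into a (side × side × slots) tensor; the network — encoder levels
  of convolution + ReLU + 2× max-pool with channels doubling from
  `base_channels`, a bottleneck, and a mirrored decoder of 2× transposed
  convolutions with channels halving and skip concatenations — maps it to a
  same-shape tensor whose slots at the target index set are trained (L2,
  Adam) against the held-out views. Slots are cropped back out,
  denormalized by the stored scale, and clipped at zero (clip events are
  reported as a QC counter). The network is implemented as a compact,
  fully seeded numpy convolution stack with hand-written backward passes,
  verified against numeric gradients; at reduced scale (32-cube inputs, a
  few base channels) it trains on one CPU core in minutes.

The packing layout (4× replication + circular pad; slot k ↔ projection
index k) is one consistent reading of a cubic-input design and is isolated
so alternatives can be swapped. At reduced widths the input is
(side, side, slots) rather than cubic.

## Metrics and statistics

RMSE is the root mean squared voxelwise difference over the full grid.
PSNR = 20·log₁₀(MAX/RMSE) with MAX the reference maximum by default
(switchable to the assessed image). SSIM uses plain (unweighted,
population) means, variances and covariance in every fully-inside sliding
window (default 3×3×3), stabilizers c₁ = (K₁L)², c₂ = (K₂L)² with
K₁ = 0.01, K₂ = 0.03 and L the reference dynamic range by default; the
implementation is tested to 1e-10 against a brute-force triple-loop
oracle. Paired comparisons use the two-sided paired Student t-test
(scipy), with Holm step-down adjustment (statsmodels; Bonferroni
selectable). Zero-variance differences raise a degenerate-data error
rather than returning a misleading p-value.

## Desk-scale defaults and problem sizes

The default experiment runs n = 10 subjects on 64³ grids with 4.42-mm
voxels and 120 views — about six minutes on one CPU core. 128³ grids are
supported. Unit and property tests run on 6³–32³ instances; the network
training check uses 20 pairs of 32-cube orbits.

## Findings on the default synthetic study

On the default cohort the `30-120SIP` arm is significantly better than
`30P` in SSIM, and both post-filtered arms are significantly worse than
`30-120SIP` in RMSE and SSIM — the orderings the comparison design is
built around. The RMSE contrast between `30-120SIP` and `30P`, while in
the expected direction for most subjects, does not reach significance
under the default conditions. The reason is instructive: because the
reconstructor uses the *exact* system model of the simulator, a 30-view
OSEM reconstruction carries almost no angular-undersampling penalty on
these smooth phantoms (its noiseless deviation from the 120-view
reconstruction is an order of magnitude below the interpolation bias of
the SIPs), so the RMSE comparison reduces to interpolation bias versus a
modest noise-smoothing gain. A learned SIP generator that also denoises —
which is precisely what distinguishes a trained network from angular
interpolation — is what tips that balance in clinical data.

## Reproducibility

Every random draw (cohort layout, Poisson noise, network initialization,
shuffling) derives from explicit integer seeds; re-running a configuration
reproduces reports bit-for-bit. Experiment outputs carry a provenance
record (full configuration and seeds) beside the CSV/JSON reports.
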