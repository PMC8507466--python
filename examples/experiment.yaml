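# Desk-scale five-arm comparison: 10 subjects, 64-cube phantoms, 120 views.
# Matches the library defaults; shrink grid_size/matrix_size and n_angles
# (keeping n_angles a multiple of 4 and divisible by recon.n_subsets) for a
# faster smoke run.
n_subjects: 10
cohort_seed: 1234
noise_seed: 5678
count_scale: 1.0e5          # expected counts per projection
sip_method: interp          # or "unet" (add network/training sections below)

phantom:
  grid_size: 64
  voxel_size_mm: 4.42
  body:
    center_mm: [0.0, 0.0, 0.0]
    semi_axes_mm: [120.0, 90.0, 110.0]
  background_activity: 1.0
  attenuation_mu: 0.0127    # mm^-1, ~water at the 245-keV photopeak

geometry:
  n_angles: 120
  angular_range_deg: 360.0
  matrix_size: 64
  pixel_size_mm: 4.42

system:
  psf_sigma0_mm: 3.0        # collimator-detector response sigma(d) = sigma0 + slope*d
  psf_slope: 0.04
  scatter_mode: none        # "kernel" adds a broad effective-scatter component
  attenuation_enabled: true

recon:
  n_subsets: 6
  n_iterations: 10

gaussian_filter:
  gaussian_sd_mm: 4.0

butterworth_filter:
  bw_order: 2
  bw_cutoff: 0.036
  cutoff_units: cycles_per_mm

metrics:
  ssim_kernel: 3
  K1: 0.01
  K2: 0.03
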