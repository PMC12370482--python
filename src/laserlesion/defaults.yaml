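# Default pipeline configuration. Every value here is a documented choice
# where the underlying method left a parameter unstated; see README.
seed: 0

rats_schedule:
  # decreasing stringency = increasing quadtree leaf size (px)
  min_leaf: [8, 16, 32, 64]
  lambda_factor: 3.0
  noise_sd: null          # null = estimate from image border (1.4826*MAD)
  significance: 0.5

masking:
  saturated_fraction: 0.0035   # contrast-enhancement tail clip
  clean_iterations: 10

orientation:
  flip_rows: false
  flip_cols: false
  rot90: 0

alignment:
  roi: ring                    # ring | pixel
  steady_state_fraction: 0.1   # tail of exposure window averaged

scoring:
  min_dead_cells: 5
  central_radius_fraction: 0.5
  min_circularity: 0.6
  footprint_tolerance: 1.05
  red_mad_factor: 5.0

analysis:
  reciprocity_tolerance: 0.10
  dose_uncertainty: 0.032      # relative; instrument band 2.8-3.2%
  fiducial_level: 0.95
  slope_gate: 5.0
  fiducial_rel_limit: 0.30

simulation:
  ambient_C: 35.5
  rise_time_constant_s: 0.4
  diffusion_sigma_um: 150.0
  camera_noise_sd_C: 0.1
  cell_density_mm2: 1500.0
  nucleus_radius_um: 6.0
  bleedthrough_coeff: 0.1
  halo_intensity_factor: 1.3
  halo_radius_factor: 0.7
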