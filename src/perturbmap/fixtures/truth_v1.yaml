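# truth_v1: modular screen with 9 planted TF modules over 45 perturbations
# and 4 planted gene programmes over 120 panel genes; noiseless capture so
# assignment is exact and clustering recovery isolates the map stage.
name: truth_v1
seeds: [201, 202, 203, 204, 205]
library_seed: 11
n_cells: 6500
min_cells: 48
n_modules: 9
targets_per_module: 5
n_programmes: 4
genes_per_programme: 30
effect_size: 1.0
ntc_weight: 9.0
dispersion: 2.0
libsize_sigma: 0.3
baseline_low: 1.0
baseline_high: 4.0
capture_noise:
  lambda_true: 15.0
  lambda_background: 0.0
  doublet_rate: 0.0
  unassigned_rate: 0.0
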