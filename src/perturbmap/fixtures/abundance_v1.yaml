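# abundance_v1: synthetic screen used for the perturbation-retention check.
# 180 gene-level targets; eight are strongly depleted (well below the
# minimum-cells filter), the rest comfortably above it.
name: abundance_v1
seed: 101
library_seed: 7
n_cells: 24000
min_cells: 48
depleted_targets: [Ezh2, Irf4, Junb, Klf2, Stat5a, Stat5b, Yy1, Zbtb32]
depleted_weight: 0.08
ntc_weight: 24.0
capture_noise:
  lambda_true: 15.0
  lambda_background: 0.0005
  doublet_rate: 0.08
  unassigned_rate: 0.12
expression:
  dispersion: 2.0
  libsize_sigma: 0.3
  dead_cell_rate: 0.03
  dead_mito_factor: 8.0
  n_background_genes: 45
  background_mean_low: 1.0
  background_mean_high: 4.0
  mito_genes: [mt-Nd1, mt-Co1, mt-Co2, mt-Atp6, mt-Cytb]
  mito_mean: 1.0
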