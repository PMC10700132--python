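# candidates_v1: four fabricated evidence datasets for the TF nomination
# pipeline. All library targets except the nine curated TFs are nominated
# (2-of-3 channels) in one or more datasets; the curated nine carry no
# multi-channel evidence and enter the final list only via curation.
name: candidates_v1
seed: 301
datasets: [tumour_scrna, chronic_lcmv_atac, early_late_rna, pex_ex_atac]
top_n: 171
curated: [Tcf7, Tox, Batf, Id2, Id3, Eomes, Prdm1, Foxo1, Bcl6]
n_extra_tfs: 40
nomination_tiers: # number of top-ranked TFs nominated in >= 4/3/2/1 datasets
  four: 40
  three: 50
  two: 50
  one: 31
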