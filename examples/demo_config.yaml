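# Scaled-down demo run of the full pipeline on the truth_v1 fixture.
out_dir: scratch/demo_run
seed: 5
fixture: truth_v1
n_cells: 4000
n_modules: 9
n_programmes: 4
run_design: true
run_interaction: true
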