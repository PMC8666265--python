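# Desk-scale benchmark: the four linear-model families, placebo and small
# effects, instantaneous adoption. Runs in a few minutes on one CPU.
# Usage: didsim run examples/desk_run.yaml --out-dir results/
baseline:
  n_states: 50
  n_years: 18
  seed: 1
model_ids:
  - twfe_linear_population
  - twfe_linear_unweighted
  - detrended_linear_unweighted
  - ar_linear_unweighted
  - gee_linear_unweighted
k_values: [5, 30]
size_classes: ["null", "small"]   # quote "null" so YAML keeps it a string
phase_ins: [instantaneous]
n_sims: 200
master_seed: 0
out_dir: results
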