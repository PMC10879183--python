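# Full-pipeline config for `survsig run --config examples/pipeline.yaml`.
# Replace the simulation block with cohort_paths/cohort_names to run on
# real expression + clinical TSV pairs.
simulation:
  n_genes: 200
  n_planted: 10
  effect_size: 0.16
  group_shift: 1.2
  n_samples_per_cohort: [150, 150, 150]
  censoring_rate: 0.3
  seed: 21
B: 100
top_k: 30
G_max: 30
de_alpha: 0.05
min_support: 2
consensus_iters: 5000
seed: 21
out_dir: scratch/pipeline_run
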