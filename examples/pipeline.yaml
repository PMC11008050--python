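# Demo pipeline config: a small synthetic AD-like study, end to end.
# Run:  dmfit run --config examples/pipeline.yaml --out demo_out
seed: 1
out_dir: demo_out

synthetic:
  n_regions: 90
  connectome_density: 0.3
  atrophy_strength: 1.5
  sigma_true: -0.2        # sigma at diagnosis (YWD -> 0)
  ywd_slope: -0.02        # planted change of sigma per year with disease
  gender_effect: -0.01    # additional slope for women
  noise_sd: 0.01
  group: AD
  n_per_cell: 12          # subjects per (group, site) cell
  n_strata: 4             # YWD bins fitted separately

dmf:
  t_total: 90.0
  t_burn: 5.0

fit:
  n_calls: 12
  n_initial: 4
  n_sim_per_eval: 1
  n_repetitions: 5

ssim:
  window: 7

progression:
  n_runs: 8
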