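# Full-pipeline demo: simulate -> fit -> predict -> diagnose
# Run from the repository root:  washord run --config examples/demo_config.yaml
out_dir: washord_demo_run
survey:
  n_clusters: 100
  households_per_cluster: [25, 30]
  K: 3
  beta: [0.8, -0.5, 0.6, 0.3]
  thresholds: [-1.0, 1.0]
  sigma_b: 0.4
  spatial_range: 3.0
  sigma_u: 0.6
  domain: [0, 10, 0, 10]
  seed: 42
  covariate_spec:
    - {name: hdi, kind: continuous, trend_sd: 1.0, noise_sd: 0.3}
    - {name: nightlight, kind: continuous, trend_sd: 1.0, noise_sd: 0.3}
    - {name: urbanicity, kind: categorical, levels: [rural, urban], probs: [0.6, 0.4]}
    - {name: time, kind: time, start: "2006-01-01", end: "2023-12-31"}
mesh:
  buffer_fraction: 0.2
  max_edge: 1.5
fit:
  use_spatial: true
  use_cluster: true
predict:
  resolution: 0.25
  date: "2024-01-01"
  component: hygiene
  class_names: [Hwash_None, Hwash_Lim, Hwash_Bas]
diagnostics:
  n_bins: 10
  n_rep: 50
  seed: 0
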