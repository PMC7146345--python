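# Default pipeline configuration.
synth:
  n_subjects: 5
  reps_per_test: 20
  sample_rate: 50.0
  subject_scale_jitter: 0.1
  classes_file: null
preprocess:
  alpha: 0.98
  median_window: 3
features:
  window_l1: {length: 10, step: 5}
  window_l3: {length: 4, step: 2}
  buffer_samples: 155
  chunk_samples: 55
model:
  k1: 70
  k2: 20
  k3: 8
  dbscan_eps: 0.2
  dbscan_min_pts: 2
  greedy_tol: 0.0
  threshold_percentile: 99.5
  min_run: 2
evaluate:
  folds: 5
seed: 0
verbosity: 1
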