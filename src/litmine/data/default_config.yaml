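# Shipped default run configuration.
model:
  K: 30            # working number of topics
  alpha: null      # null -> 50/K
  beta: 0.01
  n_iter: 1000
expansion:
  threshold: 0.95  # similarity cut-off (min of word and topic cosine)
  min_matches: 5   # accepted articles that must clear the threshold
  batch_size: 100  # candidates per training cycle
  refit_each_cycle: true
  mode: min
viz:
  lambda: 0.6
  n_terms: 30
sweep:
  K_list: [20, 25, 30, 60, 90, 120, 200]
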