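# Desk-scale configuration: reduced ensemble and shortened, coarser
# integration (steady states verified against dt=1e-3, t_dev=100 fixtures).
ensemble:
  n_networks: 10000
  model_kind: multilinear
  seed: 1
development:
  t_dev: 20.0
  dt: 0.01
  noise_enabled: false
evolution:
  pop_size: 64
  max_generations: 1500
  grain: 10.0
  target_slope: 1.0
  selected_map_kind: GP
  record_every: 100
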