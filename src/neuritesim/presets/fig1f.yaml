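# Soft-membrane sweep: projection length vs adhesion strength u3 at kappa00 = 10.
# Intermediate u3 maximizes extension; very low or high u3 restricts it.
base_config:
  dt: 1.0e-4
  n_steps: 100000
  save_every: 2000
  grow_interval: 0.1
  grow_max: 40
  protrusive_count: 1
u3_values: [0.5, 1.0, 3.0, 10.0, 30.0, 50.0]
kappa00_values: [10.0]
replicates: 5
root_seed: 20
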