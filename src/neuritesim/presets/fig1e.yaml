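# Stiff-membrane contrast: persistence of protrusions at kappa00 = 500 for
# low (3.0) vs high (30.0) membrane-actin adhesion u3.
base_config:
  dt: 1.0e-4
  n_steps: 60000
  save_every: 2000
  kappa_bend_protrusive: 500.0
  grow_interval: 0.1
  grow_max: 30
  protrusive_count: 1
u3_values: [3.0, 30.0]
kappa00_values: [500.0]
replicates: 5
root_seed: 20
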