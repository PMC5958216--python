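# Desk-scale preset: large uniform DIF, every misspecification setting,
# all three correlations, 30 replications, all three methods.
conditions: all
filters:
  dif_type: uniform
  dif_size: large
reps: 30
seed: 1
alpha: 0.05
methods: [mh, logistic, wald]
n_per_group: 1000
output: results/desk_scale
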