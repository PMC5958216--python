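# Fast score-based-only preset: skips all EM fitting (no Wald).
conditions: all
filters:
  dif_size: large
  rhos: [0.5]
reps: 50
seed: 1
alpha: 0.05
methods: [mh, logistic]
n_per_group: 1000
output: results/mh_logistic_fast
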