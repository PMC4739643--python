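# Small end-to-end synthetic configuration: 3 individuals, 6 days, 64x64
# landscape, reduced spatial basis and a 1-variable environmental candidate
# set, sized to complete on a single CPU in about a minute and a half.
seed: 1
sim:
  n_individuals: 3
  duration_days: 6
  grid_size: 64
k_space: 30
env_vars: [prop_urban_240]
n_perm: 99
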