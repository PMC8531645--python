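# Default contusim pipeline configuration.
# Seeds are explicit: there is no wall-clock randomness anywhere.
seeds:
  master: 1

output_dir: contusim_out

# Closed-form stand-in simulator constants (see docs/methods.md).
standin:
  null_mode: true

# Surrogate ensemble (paper-scale defaults: 80-point Sobol design, 72/8 split).
design_size: 80
training:
  n_members: 6

stages:
  generate: true
  train: true
  mcs: true
  sensitivity: true
  injury: true
  rate_curves: false

mcs:
  n: 10000
sensitivity:
  n: 10000
  M: 48
  B: 100
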