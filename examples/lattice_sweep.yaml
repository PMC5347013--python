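# Lattice Model 1 bystander sweep: half-time vs bystander count.
model:
  kind: lattice
  width: 12
  height: 12
  n_killers: 2
  n_targets: 8
  multiplier: 4.0
  model: model1
ensemble:
  samples: 400
  seed: 7
sweep:
  n_bystanders: [0, 10, 25]
output:
  dir: results/lattice_sweep
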