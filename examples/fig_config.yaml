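# Continuous-model reference configuration: 20 killers, 20 targets,
# 200 obstacles, 50 accelerating bystanders (D_acc = 4, zone radius 3).
model:
  kind: continuous
  n_k: 20
  n_t0: 20
  n_o: 200
  n_b: 50
  r_obs: 0.5
  D_acc: 4.0
  delta: 3.0
ensemble:
  samples: 2000
  seed: 7
output:
  dir: results/fig_config
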