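# Progressive Oscillatory Reaction-Diffusion: lateral-inhibition relay
# (k1 = 0, strong diffusion) triggered by an anterior pre-patterned somite,
# with a weak anteriorly decreasing frequency gradient.
name: PORD
k1: 0.0
k2: 1.0
k3: 1.0
k4: 1.0
D: 1.0
R: []                     # no regionalisation; all cells oscillatory
FG:
  delta_k: 0.3
  a: 0.1
  anchor: posterior
  rises: posterior
noise:
  delta_uv: 0.05
  delta_k: 0.005
posterior_zone: 25
middle_zone: 40
Ly: 10
Lx0: 70
growth_period: 2.0
duration: 400.0
init: prepatterned-somite
init_amplitude: 0.1
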