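# Clock and Wavefront: oscillatory PSM with an anterior bistable front.
name: CW
k1: 1.0
k2: 1.0
k3: 1.0
k4: 1.0
D: 0.3
R:
  - delta_k: 3.0          # front raises k1 from 1 (oscillatory) to 4 (bistable)
    a: 1.0
    anchor: anterior
    rises: anterior
FG: null
noise:
  delta_uv: 0.05
  delta_k: 0.005
posterior_zone: 25
middle_zone: 40
Ly: 10
Lx0: 70
growth_period: 2.0
duration: 400.0
init: noise
init_amplitude: 0.1
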