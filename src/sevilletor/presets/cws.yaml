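# Clock and Wavefront Self-Organizing: two-step change of k1 from the
# excitable baseline 2.3 (posterior 1.0 oscillatory, middle 2.3 excitable,
# anterior 4.0 bistable); no frequency gradient.
name: CWS
k1: 2.3
k2: 1.0
k3: 1.0
k4: 1.0
D: 0.3
R:
  - delta_k: 1.7          # anterior plateau 2.3 + 1.7 = 4.0 (bistable)
    a: 1.0
    anchor: anterior
    rises: anterior
  - delta_k: 1.3          # posterior plateau 2.3 - 1.3 = 1.0 (oscillatory)
    a: 1.0
    anchor: posterior
    rises: posterior
    sign: -1.0
FG: null                  # phase waves form without a frequency gradient
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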