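# CWS with the middle plateau replaced by a linear k1 ramp between the
# posterior (1.0) and anterior (4.0) plateau values; waves thin anteriorly.
name: CWS_graded
k1: 2.3
k2: 1.0
k3: 1.0
k4: 1.0
D: 0.3
R:
  - delta_k: 1.7
    a: 1.0
    anchor: anterior
    rises: anterior
  - delta_k: 1.3
    a: 1.0
    anchor: posterior
    rises: posterior
    sign: -1.0
FG: null
graded_middle: true
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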