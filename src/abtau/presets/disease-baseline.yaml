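# Well-mixed baseline disease scenario: uniform inflammation at the
# reference amplitudes with the fast ramp, 10-year horizon.
mode: ode
seed: 0
inflammation:
  R_star: 1.85e-6
  Rbar_star: 4.13e-10
  K: 100.0
  gamma: 1.0
  uniform_multipliers: [1.0, 1.0]
solver:
  t_end: 3650.0
  sample_interval: 10.0
output:
  directory: out/disease-baseline
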