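# Well-mixed tau-biased scenario (R = 0.5 R*, Rbar = 1.5 Rbar*).
mode: ode
seed: 0
inflammation:
  uniform_multipliers: [0.5, 1.5]
solver:
  t_end: 3650.0
output:
  directory: out/tau-biased
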