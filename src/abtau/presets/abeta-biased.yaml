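# Well-mixed amyloid-biased scenario (R = 1.5 R*, Rbar = 0.5 Rbar*).
mode: ode
seed: 0
inflammation:
  uniform_multipliers: [1.5, 0.5]
solver:
  t_end: 3650.0
output:
  directory: out/abeta-biased
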