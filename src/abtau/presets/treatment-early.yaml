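# Longitudinal treatment scenario: slow uniform ramp, drug started at
# day 2000; crossing times of the AD-average thresholds at 100-day
# imaging cadence.
mode: treatment
seed: 0
inflammation:
  K: 1000.0
  gamma: 0.7142857142857143
  uniform_multipliers: [1.0, 1.0]
solver:
  t_end: 3650.0
  sample_interval: 10.0
drug:
  t0: 2000.0
output:
  directory: out/treatment-early
  cadence: 100.0
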