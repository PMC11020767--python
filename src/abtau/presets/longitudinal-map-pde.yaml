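# Longitudinal 2-D run: non-biased map under the slow ramp
# (K = 1000, 1/gamma = 1.4), domain averages every 100 days.
mode: pde
seed: 0
inflammation:
  K: 1000.0
  gamma: 0.7142857142857143
  map:
    n_x: 10
    n_y: 10
    fractions: [0.40, 0.40, 0.15, 0.05]
    block: 5
solver:
  t_end: 3600.0
  grid_nx: 50
  grid_ny: 50
  cell_size: 0.02
  dt: 0.5
  snapshot_times: [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
                   1100, 1200, 1300, 1400, 1500, 1600, 1700, 1800, 1900,
                   2000, 2100, 2200, 2300, 2400, 2500, 2600, 2700, 2800,
                   2900, 3000, 3100, 3200, 3300, 3400, 3500, 3600]
output:
  directory: out/longitudinal-map
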