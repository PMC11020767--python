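# 2-D run with a non-biased random inflammation map (40% amyloid-biased,
# 40% tau-biased, 15% non-biased, 5% zero pixels) on a 50x50 grid of the
# unit square; snapshot at 500 days.
mode: pde
seed: 0
inflammation:
  K: 100.0
  gamma: 1.0
  map:
    n_x: 10
    n_y: 10
    fractions: [0.40, 0.40, 0.15, 0.05]
    block: 5
solver:
  t_end: 500.0
  grid_nx: 50
  grid_ny: 50
  cell_size: 0.02
  dt: 0.25
  snapshot_times: [500.0]
output:
  directory: out/nonbiased-map
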