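# Reduced-size demo configuration for `chacoedge run`.
# Omitted keys fall back to the study-scale defaults.
landscape:
  n_rows: 160
  n_cols: 160
  cell_size: 100.0
  n_plots: 20
  plot_side_range: [500.0, 1500.0]
  placement_margin: 4000.0
  n_homesteads: 15
  n_roads: 4
sampling:
  n: 1500
  max_distance: 2000.0
  boundary_buffer: 3000.0
model:
  include_age: false
  chains: 2
  iterations: 2000
  warmup: 500
metrics:
  fraction: 0.9
  grid_step: 1.0
footprint:
  threshold: 0.10
variables: [tree_cover, shrub_cover, agb]
seed: 7
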