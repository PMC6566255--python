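# Ventral (gold-green) wing side: cuboid model dimensions in nm
geometry:
  p_xy: 260
  d_a: 195
  d_b: 65
  w_a: 130
  w_b: 130
  c: 32.5
  n_stories: 4
media:
  n_chitin: [1.56, 0.033]
  n_ethanol: 1.36
wholewing:
  background: {intercept: 0.10, slope: 5.0e-5}
  sigma_nm: 15.0
  low_window: [200, 250]
  high_window: [750, 800]
  floor: 1.0e-4
fit:
  x_fit: 0.5
  s_bounds: [0.0, 0.05]
  s_grid_points: 26
  window: [200, 800]
  peak_window: [400, 700]
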