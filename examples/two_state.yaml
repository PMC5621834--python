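# Two-state chromatin-binding model at the cohesin-depleted operating point:
# 44% bound at equilibrium, 22 s residence time, D_free = 0.79 µm²/s.
model:
  bound_fraction: 0.44
  residence_time: 22.0
  D_free: 0.79
geometry:
  semi_axes: [8.0, 8.0]
  site_layout: uniform
acquisition:
  dt: 0.015503875968992248   # 64.5 frames/s
  exposure: 0.015
  pixel_size: 0.096
  sigma_loc: 0.025
  psf_sigma: 0.11
  photons_per_frame: 500.0
  background_photons: 200.0
  camera_offset: 100.0
  camera_gain: 2.0
  read_noise: 2.0
protocol:
  kind: disc
  center: [0.0, 0.0]
  radius: 1.25               # "2.5 µm circle" read as a diameter
  edge_sigma: 0.25
  n_prebleach: 10
  prebleach_dt: 2.0
  frame_times: [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0,
                15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0]
seed: 1
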