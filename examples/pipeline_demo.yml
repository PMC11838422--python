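# Small demonstration configuration for `geci report` / `geci simulate-movie`.
# Any key omitted here falls back to the shipped contamination defaults
# (wide-field preset, 128x128 um at 1 um/px, 30 neurons).
seed: 1
scene:
  n_neurons: 12
  fov: [96.0, 96.0]
  pixel_size: 1.0
  modality: widefield
  targeting: non_targeted
  neurite_count: 4
  neurite_length: 200.0
activity:
  frame_rate: 10.0
  duration_s: 45.0
  rate_independent_hz: 0.3
  rate_shared_hz: 0.04
  participation: 0.5
indicator:
  name: FRCaMPi
  kd: 81.0        # nM
  hill_n: 3.1
  f_apo: 1.0
  f_sat: 16.3     # dynamic range 16.3 with f_apo = 1
noise:
  photons_per_unit: 200.0
  read_noise_sd: 0.0
analysis:
  neuropil_r: 0.7
  annulus_inner_px: 5.0
  annulus_outer_px: 15.0
  distance_bins_um: [0, 200, 400, 800]
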