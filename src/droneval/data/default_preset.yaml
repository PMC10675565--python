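# Default simulated-flight preset: three dolphins, three camera treatments.
# Depth-detectability values are illustrative; only their ordering
# (RGB > GREEN > GREEN_POL) is a claimed property of the preset.
n_frames: 3000
seed: 42
frame_width: 3840
frame_height: 2160
fps: 30
light_gamma: 0.5
annotation_margin: 1.0
max_extension: 60
heading_noise_sd: 0.03
flight_id: sim
class_label: dolphin
camera_offsets:
  RGB: 0
  GREEN: 1
  GREEN_POL: 0
animals:
  - animal_id: a1
    start_x: 1200.0
    start_y: 900.0
    speed: 2.0
    heading: 0.3
    surface_duration: 60
    dive_duration: 240
    max_depth: 6.0
    body_width: 60.0
    body_height: 25.0
    cycle_phase: 0
  - animal_id: a2
    start_x: 2400.0
    start_y: 1300.0
    speed: 1.5
    heading: 2.2
    surface_duration: 80
    dive_duration: 200
    max_depth: 5.0
    body_width: 70.0
    body_height: 28.0
    cycle_phase: 90
  - animal_id: a3
    start_x: 1900.0
    start_y: 600.0
    speed: 2.5
    heading: -1.1
    surface_duration: 50
    dive_duration: 260
    max_depth: 7.0
    body_width: 55.0
    body_height: 22.0
    cycle_phase: 180
detectability:
  RGB:
    d50: 4.0
    slope: 0.5
    jitter_sd: 3.5
    fp_rate: 0.02
    light_fraction: 1.0
  GREEN:
    d50: 2.5
    slope: 0.5
    jitter_sd: 3.5
    fp_rate: 0.02
    light_fraction: 0.12
  GREEN_POL:
    d50: 1.5
    slope: 0.5
    jitter_sd: 3.5
    fp_rate: 0.02
    light_fraction: 0.06
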