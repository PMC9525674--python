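grid_shape:
- 64
- 64
- 64
voxel_spacing:
- 0.5
- 0.5
- 0.5
noise_sd_low: 542.0
noise_sd_high: 542.0
seed: 7
artifact:
  band_width: 2
  offset: 300.0
regions:
- label: bone
  geometry:
    type: ellipsoid
    center:
    - 31.5
    - 31.5
    - 31.5
    radii:
    - 20.48
    - 14.72
    - 14.72
  composition:
    fluorite: 0.5112
    calcite: 0.37382
    background: 0.11498
- label: sediment
  geometry:
    type: difference
    outer:
      type: box
      lo:
      - 2
      - 2
      - 2
      hi:
      - 62
      - 62
      - 62
    inner:
      type: ellipsoid
      center:
      - 31.5
      - 31.5
      - 31.5
      radii:
      - 20.48
      - 14.72
      - 14.72
  composition:
    calcite: 0.45
    background: 0.55
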