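b1_range:
- 115.0
- 180.0
background_M0: 0.5
background_T1: 1000.0
background_T2: 60.0
body_semi_axes:
- 30.0
- 30.0
boundary_policy: pure
compartments:
- M0: 1.0
  T1: 4000.0
  T2: 2000.0
  center:
  - 32
  - 14
  - 6
  label: 1
  semi_axes:
  - 5
  - 5
  - 20
- M0: 0.765
  T1: 1000.0
  T2: 95.0
  center:
  - 18
  - 34
  - 3.5
  label: 10
  semi_axes:
  - 5
  - 4
  - 2.6
- M0: 0.765
  T1: 1000.0
  T2: 95.0
  center:
  - 46
  - 34
  - 3.5
  label: 11
  semi_axes:
  - 5
  - 4
  - 2.6
- M0: 0.765
  T1: 1000.0
  T2: 95.0
  center:
  - 18
  - 48
  - 8.5
  label: 20
  semi_axes:
  - 5
  - 4
  - 2.6
- M0: 0.765
  T1: 1000.0
  T2: 95.0
  center:
  - 46
  - 48
  - 8.5
  label: 21
  semi_axes:
  - 5
  - 4
  - 2.6
drg_M0: 0.765
noise_sigma: 0.0
seed: 0
shape:
- 64
- 64
- 12
supersample: 3
voxel_dims:
- 1.5
- 1.5
- 1.8
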