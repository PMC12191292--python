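aggregation_convention: pooled_voxel_median
assumed_T1: 1000.0
csf_min_component: 10
csf_percentile: 98.0
csf_t2_min: 400.0
echo_spacing: 15.0
fit_tol: 0.0001
max_iter: 25
min_csf_voxels: 20
n_echoes: 10
noise_floor: 0.0
nominal_flip: 180.0
percentile_convention: linear
repetition_time: 4.8
seed: 0
slice_axis: -1
voxel_dims:
- 1.5
- 1.5
- 1.8
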