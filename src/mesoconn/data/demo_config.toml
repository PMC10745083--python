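# Demo pipeline configuration: a small synthetic brain, EL estimator with
# LOOCV hyperparameter selection, connectivity tensor, and masked sparse NMF.

[run]
seed = 0
log_level = "INFO"
out = "scratch/demo"

[simulate]
enabled = true
n_major = 2
leafs_per_major = 2
leaf_shape_voxels = [3, 3, 3]
n_classes = 3
pattern_sparsity = 0.5
class_effect = 1.0
smoothness_scale_um = 1000.0
n_per_cell = 3
noise_sd = 0.2

[estimator]
kind = "el"
normalization = "total_projection"
sigma_x_grid = [100.0, 300.0, 800.0]
sigma_c_grid = [0.1, 1.0]
alpha_grid = [0.0, 0.5, 1.0]
mode = "structure"

[mask]
threshold_um = 400.0
mode = "min_voxel"

[nmf]
q = 3
lambda = 0.002
replicates = 5
matrix_class = "wt"
variant = "normalized"
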