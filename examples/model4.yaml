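# Full model-4 pipeline on a small synthetic phantom set.
model: model4
phantom:
  n_samples: 36
  shape: [28, 28, 28]
  noise_sd: 0.02
  jitter_voxels: 1
  class_radius_deltas: [0.0, 1.2, 2.4]
input_shape: [28, 28, 28]
width_scale: 0.25        # shrink conv widths for CPU runs; 1.0 = full size
fc_width: 1000
cnn_train:
  epochs: 30
  batch_size: 8
  learning_rate: 0.001
resnet_train:
  epochs: 30
  batch_size: 8
  learning_rate: 0.001
  early_stopping_patience: 10
fusion_lam: 0.001
fusion_d: 4
fusion_mode: Z1_concat
optimizer:
  algorithm: woa
  population: 10
  iterations: 15
  independent_runs: 1
fitness:
  alpha: 0.99
  knn_k: 5
  n_splits: 5
classifier: gb
k_folds: 5
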