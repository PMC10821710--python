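# 3D label-free with center normalization and an anisotropic U-Net:
# early levels downsample only laterally because Z resolution is coarser.
data:
  mode: paired_folders
  data_path: data/labelfree3d
  source_key: image
  target_key: ground_truth
  val_fraction: 0.2
preprocess:
  - {name: center_normalize, params: {center_fraction: 0.5}, deterministic: true, apply_to: source}
  - {name: percentile_normalize, params: {lo: 0.5, hi: 99.5, out_range: [-1, 1]}, deterministic: true, apply_to: target}
sampling:
  patch_size: [8, 32, 32]
  patches_per_image: 2
framework:
  kind: fcn
  recon_loss: mae
  task: regression
network:
  name: unet_aniso_3d
  dim: 3
  in_channels: 1
  out_channels: 1
  depth: 3
  base_filters: 8
  down_factors: [[1, 2, 2], [2, 2, 2]]
  final_activation: tanh
trainer:
  max_epochs: 10
  batch_size: 2
  seed: 42
inference:
  window_size: [8, 32, 32]
  overlap: 0.25
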