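# 2D semantic segmentation of H&E-like tiles with Reinhard stain normalization
# (ref_means/ref_stds are CIELAB statistics of a chosen reference tile).
data:
  mode: paired_folders
  data_path: data/stain2d
  source_key: image
  target_key: ground_truth
  val_fraction: 0.2
preprocess:
  - {name: stain_normalize, params: {ref_means: [72.0, 18.0, -8.0], ref_stds: [14.0, 8.0, 6.0]}, deterministic: true, apply_to: source}
  - {name: minmax_normalize, params: {out_range: [0, 1]}, deterministic: true, apply_to: source}
sampling:
  patch_size: [64, 64]
  patches_per_image: 4
framework:
  kind: fcn
  recon_loss: mse
  task: segmentation
network:
  name: unet_2d
  dim: 2
  in_channels: 3
  out_channels: 1
  depth: 3
  base_filters: 16
  final_activation: sigmoid
trainer:
  max_epochs: 10
  batch_size: 4
  seed: 42
inference:
  window_size: [64, 64]
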