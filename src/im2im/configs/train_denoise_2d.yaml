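# Supervised denoising: low-SNR source, high-SNR target of the same scene.
data:
  mode: csv_manifest
  data_path: data/denoise2d
  val_fraction: 0.2
preprocess:
  - {name: percentile_normalize, params: {lo: 0.5, hi: 99.5, out_range: [-1, 1]}, deterministic: true}
sampling:
  patch_size: [64, 64]
  patches_per_image: 4
framework:
  kind: fcn
  recon_loss: mse
  task: regression
network:
  name: unet_2d
  dim: 2
  in_channels: 1
  out_channels: 1
  depth: 3
  base_filters: 16
  final_activation: tanh
trainer:
  max_epochs: 10
  batch_size: 4
  seed: 42
inference:
  window_size: [64, 64]
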