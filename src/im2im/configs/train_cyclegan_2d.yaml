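# CycleGAN: unpaired two-domain translation (e.g. mask <-> image);
# both mapping directions are usable at inference.
data:
  mode: paired_folders
  data_path: data/unpaired2d
  source_key: domain_a
  target_key: domain_b
  val_fraction: 0.2
preprocess:
  - {name: percentile_normalize, params: {lo: 0.5, hi: 99.5, out_range: [-1, 1]}, deterministic: true}
sampling:
  patch_size: [64, 64]
  patches_per_image: 2
framework:
  kind: cyclegan
  cycle_weight: 10.0
  identity_weight: 5.0
  adv_weight: 1.0
  gan_objective: lsgan
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
  max_epochs: 20
  batch_size: 2
  learning_rate: 2.0e-4
  seed: 42
inference:
  window_size: [64, 64]
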