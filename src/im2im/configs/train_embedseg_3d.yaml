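# 3D EmbedSeg with an anisotropic backbone: datasets with few Z slices cannot
# pass isotropic downsampling, so Z factors stay 1 in early levels.
data:
  mode: csv_manifest
  data_path: data/instance3d
  val_fraction: 0.2
preprocess:
  - {name: center_normalize, params: {center_fraction: 0.5}, deterministic: true, apply_to: source}
sampling:
  patch_size: [8, 32, 32]
  patches_per_image: 2
  weighting: foreground_weighted
framework:
  kind: embedseg
  embedseg:
    center_mode: medoid
    per_axis_sigma: true
network:
  name: unet_aniso_3d
  dim: 3
  in_channels: 1
  out_channels: 7   # 3 offsets + 3 per-axis sigma + seed
  depth: 3
  base_filters: 8
  down_factors: [[1, 2, 2], [1, 2, 2]]
trainer:
  max_epochs: 30
  batch_size: 2
  seed: 42
inference:
  window_size: [8, 32, 32]
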