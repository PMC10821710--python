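# 2D EmbedSeg-type instance segmentation with exclusion-mask support.
data:
  mode: csv_manifest
  data_path: data/instance2d
  val_fraction: 0.2
preprocess:
  - {name: percentile_normalize, params: {lo: 0.5, hi: 99.5, out_range: [-1, 1]}, deterministic: true, apply_to: source}
sampling:
  patch_size: [64, 64]
  patches_per_image: 2
  weighting: foreground_weighted
  fg_ratio: 0.5
framework:
  kind: embedseg
  embedseg:
    center_mode: medoid
    fg_threshold: 0.5
    seed_threshold: 0.9
    min_size: 2
    bg_margin: 8
network:
  name: unet_2d
  dim: 2
  in_channels: 1
  out_channels: 4   # 2 offsets + sigma + seed
  depth: 3
  base_filters: 16
trainer:
  max_epochs: 30
  batch_size: 4
  learning_rate: 1.0e-3
  seed: 42
inference:
  window_size: [64, 64]
  overlap: 0.25
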