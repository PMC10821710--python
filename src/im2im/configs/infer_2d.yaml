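# Inference-only: sliding-window prediction with Gaussian blending.
data:
  mode: csv_manifest
  data_path: data/labelfree2d
  val_fraction: 0.0
preprocess:
  - {name: percentile_normalize, params: {lo: 0.5, hi: 99.5, out_range: [-1, 1]}, deterministic: true}
framework:
  kind: fcn
  task: regression
network:
  name: unet_2d
  dim: 2
  in_channels: 1
  out_channels: 1
  depth: 3
  base_filters: 16
  final_activation: tanh
inference:
  window_size: [64, 64]
  overlap: 0.25
  blend: gaussian
  gaussian_sigma_scale: 0.125
  un_normalize: true
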