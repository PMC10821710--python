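# Methods

This note documents the models, numerical choices and limitations of the
`im2im` package: a configurable engine for microscopy image-to-image
transformation covering supervised pixel regression (FCN), conditional
adversarial translation (pix2pix), unsupervised cycle-consistent translation
(CycleGAN) and embedding-based instance segmentation (EmbedSeg-type), over one
shared data model.

## Data model and axis conventions

Images are axis-labeled arrays over a subsequence of T, C, Z, Y, X with Y and
X mandatory. The canonical in-memory order is TCZYX (the OME convention);
CTZYX on disk is read as a dialect and transposed on load. Canonicalization is
idempotent. Physical voxel sizes (microns per spatial axis) ride along and are
written into OME-TIFF metadata. Files without axis metadata are interpreted by
rank: 2→YX, 3→ZYX, 4→CZYX, 5→TCZYX.

Reading is deferred at image granularity: opening a file records its axes and
calibration, and pixels are materialized on first access. Plane-level lazy
slicing (chunked/zarr-backed access) is out of scope; for the image sizes this
package targets, whole-image deferral is the operative optimization (images
are not read at manifest-build time at all).

## The neural-network engine

No deep-learning runtime is a dependency: the package carries a small
reverse-mode automatic-differentiation engine over float32 numpy arrays
(`im2im.nn`). The op set is exactly what the built-in backbones and losses
need: elementwise arithmetic and nonlinearities, reductions, N-dimensional
strided convolution (im2col via stride tricks; the input-gradient scatter
loops over kernel offsets), nearest-neighbour upsampling, concatenation,
slicing, padding, and instance/batch normalization composed from primitives.
Correctness is certified by central-difference gradient checks in the test
suite. Adam is the only optimizer. Everything is single-threaded,
deterministic float32: two runs with the same seed and config produce
bitwise-identical loss traces on one CPU.

The cost of this choice is speed — training throughput is roughly an order of
magnitude below a compiled runtime — which the package absorbs by targeting
desk-scale problems: 64² (2D) or 8×32×32 (3D) patches, tiny U-Nets, and
hundreds rather than hundreds of thousands of steps.

## Backbones

A single dimension-generic U-Net serves 2D and 3D. `depth` counts resolution
levels; `depth − 1` down transitions each carry per-axis integer factors, so
anisotropy is a configuration, not a separate architecture: a transition with
Z factor 1 downsamples only laterally and uses flat-Z (1×3×3) kernels. A
volume with 4 Z slices therefore passes through a 4-level network when all Z
factors are 1, which is the standard accommodation for microscopy stacks whose
axial extent is far below their lateral extent. Downsampling is by strided
convolution (kernel = stride = factor), upsampling by nearest-neighbour repeat
followed by 1×1 convolution and skip concatenation. Feature widths double per
level from `base_filters`. Generators default to instance normalization, the
PatchGAN discriminator (3 stride-2 blocks; 64² input → 8² logit grid) to batch
normalization; both are per-layer configurable. External architectures are
reachable by dotted import path; every resolved network is probe-checked
(forward pass on a minimal valid input, output channels verified) before use.

## Normalization

All intensity normalizations are per channel, per image:

* **percentile** (default lo 0.5, hi 99.5, out_range (−1, 1); estimator =
  linear interpolation between order statistics): clip to [P_lo, P_hi], map
  affinely. (0, 1) is available by config.
* **standard**: z-score with population std.
* **center** (3D only; `center_fraction` default 0.5): z-score the whole
  volume using statistics of the middle ⌈fraction·Z⌉ planes, where the
  in-focus content lives; degenerates exactly to standard at fraction 1.
  The chunk is a fraction, not a fixed plane count, so the same config works
  across stacks of different depth.

Inversion: affine normalizations invert exactly from per-image stats cached at
normalization time; z-score outputs are left in z-score space at inference
unless stats are available, with a logged notice.

Stain normalization for H&E tiles is Reinhard-style: per-channel mean/std
transfer in CIELAB against a reference tile's statistics, clipped back to the
valid RGB range. It is registered as `stain_norm: reinhard` in configs so
alternative transfers can be added; stain-vector deconvolution is a declared
non-goal.

Constant images (zero spread where statistics are required) raise a
degenerate-intensity error rather than emitting NaNs.

## Data handling

Four manifest modes cover the common layouts: a CSV manifest (columns
`source_path,target_path[,exclusion_path][,weight_path]`), paired folders
matched by filename, a suffix convention (`stem_IM`/`stem_GT`/`stem_EM`)
matched by stem, and pre-split train/val subtrees. Record order is
lexicographic by source path; the train/val split draws from the run's seed
tree, so a manifest is a pure function of (tree, config, seed). Orphaned
files and missing targets fail fast with the offending stems or rows named.

Deterministic transforms (normalization, padding) run once per record and are
cached on disk, keyed by a SHA-256 digest of (file path, mtime, serialized
transform list, source/target role); any parameter change invalidates the key.
Collections too large for memory are handled by portion reloading: each reload
period draws ⌈fraction·N⌉ records from a seeded permutation that continues
across periods, so every record is visited before any repeats (coverage within
⌈1/fraction⌉ periods).

## Patch sampling and exclusion masks

Patch origins are drawn from the valid-origin set only — patches never cross
image boundaries, so no synthetic borders enter any loss. With
`foreground_weighted` sampling, a patch is centered on a positive voxel of the
weight map (or target foreground) with probability `fg_ratio` (default 0.5 — a
balance between background coverage and instance coverage), else uniformly;
an all-zero weight map falls back to uniform with a warning. Source, target,
exclusion and weight crops share the window exactly.

Exclusion masks (1 = excluded) remove voxels from every loss term: losses are
means over kept voxels, so the gradient at excluded voxels is identically
zero. A patch lying entirely in an excluded region is resampled (up to 10
attempts); a fully excluded batch element is an error. This supports partially
annotated ground truth — e.g. instance labels that are uncurated for
border-touching cells.

## Frameworks

* **FCN**: masked reconstruction loss (MAE default; MSE, smooth-MAE
  available), one Adam optimizer (lr 1e-3).
* **pix2pix**: generator loss λ_rec·recon + λ_adv·adv with a conditional
  PatchGAN discriminator on (source, candidate) channel concatenation;
  discriminator loss ½[adv(real)+adv(fake, generator detached)].
  Defaults λ_rec 100, λ_adv 1, lsgan objective, Adam lr 2e-4 β=(0.5, 0.999)
  — the originating conventions, all YAML-overridable. At λ_adv = 0 the
  generator update equals the FCN update exactly (a tested invariant). The
  generator can be pre-initialized from an FCN checkpoint and then reproduces
  its outputs bitwise before the first update.
* **CycleGAN**: two generators, two discriminators, unpaired batches;
  λ_cyc 10, λ_id 5, λ_adv 1. Both directions usable at inference. No replay
  buffer (a config hook reserves the option).

GAN objectives operate on sigmoid-squashed discriminator outputs: lsgan is a
squared error against 1/0 targets in probability space (so a discriminator
emitting 0.5 everywhere scores exactly 0.25), vanilla is log-sigmoid.

## EmbedSeg-type instance segmentation

Per pixel the network predicts a tanh-limited spatial offset o_i, a bandwidth
σ_i = exp(raw_i) (optionally per axis for anisotropic data), and a seediness
s_i. Coordinates are normalized per axis to [0, 1). For instance k with
center C_k (medoid by default — always inside non-convex instances; centroid
available), membership is scored by the Gaussian
φ_k(e_i) = exp(−‖e_i − C_k‖²/(2σ_k²)) with e_i = x_i + o_i and σ_k the
instance mean of σ. The loss combines:

1. a class-balanced binary cross-entropy of φ_k against membership, evaluated
   over the instance plus nearby background (bounding box dilated by
   `bg_margin`, default 8 voxels — the spec leaves "nearby" open and a fixed
   margin is predictable); the foreground side is computed directly on the
   exponent (−log φ = ‖e−C‖²/2σ²), which stays differentiable when φ
   underflows, and the two sides are balanced so small instances are not
   drowned out by background;
2. a sigma-smoothness term: variance of σ within each instance (weight 10);
3. a seed-regression term: squared error of s toward φ_k (detached) on
   instance pixels and toward 0 on background (weight 1).

Centers are recomputed per patch after cropping, so augmented geometry is
always consistent — no precomputed center images exist anywhere.

Two head parameterizations compensate for short training budgets under an
adaptive-moment optimizer (which moves each parameter by roughly lr per
step): the seed head applies a fixed gain of 5 before the sigmoid so the map
can reach the saturated values the decoder keys on, in the same spirit as the
original method's scaled exponent for its bandwidth head.

Decoding is iterative clustering: candidates are pixels with seed >
`fg_threshold` (0.5); while the best unassigned candidate exceeds
`seed_threshold` (0.9) it becomes a cluster center (its embedding and sigma),
absorbing unassigned candidates with φ > 0.5; clusters below `min_size`
(2 voxels) are discarded; ties break by voxel order, so decoding is
deterministic. Because assignment is by embedding distance only, one instance
may comprise several disconnected components — complex shapes with holes or
detached fragments are representable. Tiled inference decodes per window and
merges instances across overlaps by IoU ≥ 0.5 relabeling.

## Sliding-window inference

Up-to-5D inputs are processed per timepoint with channels fed jointly.
Spatial axes are reflect-padded to the network's divisibility requirement,
tiled with stride = window·(1 − overlap) (default overlap 0.25) and
end-aligned final windows, predicted, and fused with a separable Gaussian
weight (σ = 0.125 × window size per axis, amplitude 1 at the window center,
floored at 1e-6 to guarantee strictly positive coverage). The fused image is
the voxelwise quotient of the weighted accumulator by the weight accumulator;
a zero weight anywhere is reported as an internal tiling bug, never silently
filled. For an identity model the quotient reproduces the input to float
tolerance at any overlap (partition of unity); Gaussian weighting strictly
reduces window-edge disagreement relative to uniform averaging. Integer
output dtypes are clipped to their representable range before casting.

## Metrics

Pearson (all voxels flattened), SSIM (7-wide uniform window, K1 = 0.01,
K2 = 0.03; 3D as plane-averaged 2D with a volumetric-window flag), PSNR
(10·log10(range²/MSE), +inf sentinel at MSE 0), pixel F1 (empty-vs-empty
defined as 1.0), and AP at IoU 0.5 defined as TP/(TP+FP+FN) with greedy
one-to-one matching by descending IoU — the instance-segmentation community
convention. Summaries are mean ± population std. Pixel SSIM/PSNR delegate to
scikit-image; AP is implemented here and tested against a brute-force optimal
assignment oracle.

## Synthetic fixtures

The generator places non-overlapping random ellipses/ellipsoids ("nuclei")
with per-object amplitude and smooth interior texture, rendered through a
Gaussian PSF (σ 1 px) onto a 0.1 background with Gaussian read noise (σ 0.05,
optional Poisson). Defaults — 64² / 8×32×32 canvases, 2–6 objects — define
the package's reference test conditions. Task renderings: label-free (source
= inverted + edge-enhanced + heavily blurred; an identity model correlates
< 0.5 with the target, so learning is measurable), semantic (binarized
labels), instance (labels + a border-touch exclusion mask), denoising
(6× vs 0.5× noise of one world), modality (heavy vs light blur), and
H&E-like RGB via two Beer–Lambert stain vectors with per-image color jitter.
3D objects are flattened along Z to emulate anisotropy. The written fixtures
carry the 0.108 × 0.108 µm lateral / 0.29 µm axial calibration typical of
100× light microscopy.

What these fixtures do **not** emulate: optical aberrations, depth-dependent
blur, camera-specific noise statistics, instance crowding/touching, and
stain co-localization structure. Passing the recovery tests therefore shows
the machinery trains and decodes correctly end to end, not that any
biological benchmark value is reproduced.

## Reference problem sizes

The shipped configurations and the reproduction script use desk-scale
problems chosen to exercise every code path with a tiny CPU footprint: the
2D label-free task trains a depth-3, 16-filter U-Net for ~300 steps on ten
64² images (8 train / 2 held out); the instance task trains the same backbone
with an EmbedSeg head for ~300 steps on ten two-object worlds, reporting the
3-seed median AP. Determinism is demonstrated by re-running the label-free
task and comparing final losses bitwise.

## Known limitations

* Throughput: numpy convolution; not intended for production-scale training.
* `precision: "16-mixed"` is accepted for config compatibility but runs in
  float32 (no mixed-precision backend); the determinism contract is stated
  for full precision.
* Stochastic weight averaging is a plain trailing average of generator
  weights across epochs when enabled — a contract-level hook, not a tuned
  schedule. Automatic batch-size/learning-rate finders are non-goals.
* EmbedSeg recovery at a ~300-step budget is sensitive to the optimizer seed;
  the package reports the 3-seed median, and longer schedules are the remedy
  on real data.
* The evaluation CLI matches predictions to records by filename stem; no
  content hashing.
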