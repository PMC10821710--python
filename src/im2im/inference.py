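"""Full-image prediction for up-to-5D inputs.

A model trained on small patches is applied to arbitrarily large images by
tiling the spatial axes into overlapping windows, predicting each window, and
fusing the predictions with a spatial weight. Gaussian weights (σ per axis =
``gaussian_sigma_scale`` × window size) down-weight window borders, where
convolutional predictions are least reliable, and remove visible stitching
seams; a weight floor of 1e-6 guarantees full coverage so the final quotient is
defined everywhere. Timepoints are processed independently; channels are fed
jointly.
"""

from __future__ import annotations

import logging

import numpy as np

from .core.axes import AxisSpec, NDImage
from .core.config import InferenceSpec, NetworkSpec, TransformSpec
from .preprocess import CropRecord, apply_transform, pad_to_valid, un_normalize_array

log = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-6


class CoverageError(RuntimeError):
    """A voxel received zero total weight — a tiling bug, not a data problem."""


def gaussian_window_weights(
    window_size: tuple[int, ...], sigma_scale: float = 0.125
) -> np.ndarray:
    """Separable Gaussian, amplitude 1 at the window center, floored at 1e-6."""
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be > 0")
    weight = np.ones((), dtype=np.float64)
    for size in window_size:
        sigma = sigma_scale * size
        center = (size - 1) / 2.0
        ax = np.exp(-((np.arange(size) - center) ** 2) / (2.0 * sigma**2))
        weight = weight[..., None] * ax if weight.ndim else ax
    return np.maximum(weight, WEIGHT_FLOOR).astype(np.float32)


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent); the final window is end-aligned."""
    if window >= extent:
        return [0]
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def stitch(
    accumulator: np.ndarray,
    weight_accumulator: np.ndarray,
    output_dtype: str = "float32",
) -> np.ndarray:
    """Voxelwise quotient, then cast with clipping to the dtype's range."""
    if np.any(weight_accumulator <= 0):
        raise CoverageError("tiling left voxels with zero accumulated weight")
    out = accumulator / weight_accumulator
    dtype = np.dtype(output_dtype)
    if dtype.kind in "ui":
        info = np.iinfo(dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(dtype)


def sliding_window_predict(
    volume: np.ndarray,
    model,
    window_size: tuple[int, ...],
    overlap: float = 0.25,
    blend: str = "gaussian",
    sigma_scale: float = 0.125,
    out_channels: int | None = None,
) -> np.ndarray:
    """Tile a (C, *spatial) volume, predict each window, blend, return (C', *spatial).

    ``model`` maps (1, C, *window) float32 → (1, C', *window).
    """
    spatial = volume.shape[1:]
    window = tuple(min(w, s) for w, s in zip(window_size, spatial))
    if window != tuple(window_size):
        log.info("window %s shrunk to %s to fit image", tuple(window_size), window)
    stride = tuple(max(1, int(round(w * (1.0 - overlap)))) for w in window)
    weights = (
        gaussian_window_weights(window, sigma_scale)
        if blend == "gaussian"
        else np.ones(window, dtype=np.float32)
    )

    probe_sl = (None, slice(None)) + tuple(slice(0, w) for w in window)
    first = model(volume[probe_sl].astype(np.float32))
    n_out = first.shape[1] if out_channels is None else out_channels

    acc = np.zeros((n_out,) + spatial, dtype=np.float64)
    wacc = np.zeros(spatial, dtype=np.float64)
    starts_per_axis = [
        _window_starts(s, w, st) for s, w, st in zip(spatial, window, stride)
    ]
    mesh = np.meshgrid(*[np.arange(len(s)) for s in starts_per_axis], indexing="ij")
    for idx in zip(*(m.ravel() for m in mesh)):
        origin = tuple(starts_per_axis[a][i] for a, i in enumerate(idx))
        sl = tuple(slice(o, o + w) for o, w in zip(origin, window))
        pred = model(volume[(None, slice(None)) + sl].astype(np.float32))[0]
        acc[(slice(None),) + sl] += pred * weights
        wacc[sl] += weights
    return (acc / np.maximum(wacc, WEIGHT_FLOOR)).astype(np.float32)


def predict_image(
    img: NDImage,
    model,
    spec: InferenceSpec,
    preprocess: list[TransformSpec] | None = None,
    network: NetworkSpec | None = None,
    decoder=None,
) -> NDImage:
    """Normalize, tile, predict, blend and un-pad a full image (up to 5D).

    ``model`` maps (1, C, *spatial) → (1, C', *spatial) numpy arrays.
    ``decoder``, when given, post-processes each timepoint's blended output
    (e.g. instance decoding); it receives and returns (C', *spatial).
    """
    img = img.canonicalize()
    labels = img.axes.labels
    data = np.asarray(img.data, dtype=np.float32)
    if "T" not in labels:
        data = data[None]
    if "C" not in labels:
        data = data[:, None]
    # data is now (T, C, *spatial)
    spatial_rank = len(img.axes.spatial)

    factors = (1,) * spatial_rank
    if network is not None and network.down_factors:
        f = [1] * spatial_rank
        for fs in network.down_factors:
            for a, v in enumerate(fs):
                f[a] *= v
        factors = tuple(f)
    elif network is not None:
        factors = (2 ** (network.depth - 1),) * spatial_rank

    window = tuple(spec.window_size) if spec.window_size else data.shape[2:]
    window = tuple(-(-w // f) * f for w, f in zip(window, factors))

    frames = []
    stats_per_frame = []
    for t in range(data.shape[0]):
        vol = data[t]
        stats: dict = {}
        if preprocess:
            for tr in preprocess:
                if tr.apply_to in ("both", "source"):
                    vol = _apply_with_stats(tr, vol, stats)
        vol_p, crop = pad_to_valid(vol, factors)
        out = sliding_window_predict(
            vol_p,
            model,
            window_size=window,
            overlap=spec.overlap,
            blend=spec.blend,
            sigma_scale=spec.gaussian_sigma_scale,
        )
        out = out[(slice(None),) + tuple(slice(0, s) for s in crop.original_shape)]
        if decoder is not None:
            out = decoder(out)
        if spec.un_normalize and stats:
            if all(s.get("method") in ("percentile", "minmax") for s in stats.values()):
                if out.shape[0] == len(stats):
                    out = un_normalize_array(out, stats)
                else:
                    log.info("un_normalize skipped: channel count changed")
            else:
                log.info(
                    "un_normalize: z-score normalization left in place; output "
                    "remains in z-score space"
                )
        frames.append(out)
        stats_per_frame.append(stats)

    result = np.stack(frames)  # (T, C', *spatial)
    out_labels = "TC" + img.axes.spatial
    if "T" not in labels:
        result = result[0]
        out_labels = "C" + img.axes.spatial
    if result.shape[out_labels.index("C")] == 1 and "C" not in labels:
        result = np.squeeze(result, axis=out_labels.index("C"))
        out_labels = out_labels.replace("C", "")
    dtype = np.dtype(spec.output_dtype)
    if dtype.kind in "ui":
        info = np.iinfo(dtype)
        result = np.clip(np.rint(result), info.min, info.max)
    result = result.astype(dtype)
    return NDImage(result, AxisSpec(out_labels), voxel_size=img.voxel_size)


def _apply_with_stats(tr: TransformSpec, vol: np.ndarray, stats: dict) -> np.ndarray:
    from . import preprocess as pp

    if tr.name == "percentile_normalize":
        return pp.percentile_normalize_array(
            vol,
            lo=tr.params.get("lo", 0.5),
            hi=tr.params.get("hi", 99.5),
            out_range=tuple(tr.params.get("out_range", (-1.0, 1.0))),
            stats_out=stats,
        )
    if tr.name == "standard_normalize":
        return pp.standard_normalize_array(vol, stats_out=stats)
    if tr.name == "center_normalize":
        return pp.center_normalize_array(
            vol, center_fraction=tr.params.get("center_fraction", 0.5),
            stats_out=stats,
        )
    if tr.name == "minmax_normalize":
        return pp.minmax_normalize_array(
            vol, out_range=tuple(tr.params.get("out_range", (0.0, 1.0))),
            stats_out=stats,
        )
    return apply_transform(tr.name, tr.params, vol)
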