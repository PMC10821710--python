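"""Intensity and color normalization for microscopy images.

Three intensity normalizations are provided, all computed per channel over a
single image:

* **percentile** — clip to the [lo, hi] intensity percentiles, then map
  affinely onto ``out_range`` (default (−1, 1)). The percentile estimator is
  linear interpolation between order statistics.
* **standard** — z-scoring with the population standard deviation.
* **center** — z-scoring of the whole volume using statistics from only the
  middle chunk of Z planes. Out-of-focus top and bottom planes of a 3D stack
  otherwise drag the statistics; the in-focus center is the better reference.
  ``center_fraction`` (default 0.5) sets the chunk as ``ceil(fraction * Z)``
  planes centered on the mid-plane.

For H&E histology tiles a Reinhard-style stain normalization is provided:
per-channel location/scale transfer in CIELAB, mapping a tile's color
statistics onto a reference tile's.

Functions operate on bare ``(C, *spatial)`` float arrays (the in-training
currency) or on :class:`NDImage` via thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .core.axes import NDImage


class DegenerateIntensityError(ValueError):
    """The image has no intensity spread where statistics are required."""


# ---------------------------------------------------------------------------
# intensity normalization on (C, *spatial) arrays; stats per channel
# ---------------------------------------------------------------------------

def percentile_normalize_array(
    arr: np.ndarray,
    lo: float = 0.5,
    hi: float = 99.5,
    out_range: tuple[float, float] = (-1.0, 1.0),
    stats_out: dict | None = None,
) -> np.ndarray:
    if not 0 <= lo < hi <= 100:
        raise ValueError(f"need 0 <= lo < hi <= 100, got lo={lo}, hi={hi}")
    a, b = out_range
    if not a < b:
        raise ValueError(f"out_range must be increasing, got {out_range}")
    arr = np.asarray(arr, dtype=np.float32)
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        p_lo, p_hi = np.percentile(arr[c], [lo, hi])
        if p_hi == p_lo:
            raise DegenerateIntensityError(
                f"channel {c}: percentiles P{lo}=P{hi}={p_lo}; constant image?"
            )
        clipped = np.clip(arr[c], p_lo, p_hi)
        out[c] = (clipped - p_lo) / (p_hi - p_lo) * (b - a) + a
        if stats_out is not None:
            stats_out[c] = {"method": "percentile", "p_lo": float(p_lo),
                            "p_hi": float(p_hi), "a": float(a), "b": float(b)}
    return out


def standard_normalize_array(
    arr: np.ndarray, stats_out: dict | None = None
) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        mu = float(arr[c].mean())
        sd = float(arr[c].std())  # population std
        if sd == 0:
            raise DegenerateIntensityError(f"channel {c}: zero standard deviation")
        out[c] = (arr[c] - mu) / sd
        if stats_out is not None:
            stats_out[c] = {"method": "standard", "mu": mu, "sd": sd}
    return out


def center_chunk_bounds(n_z: int, fraction: float) -> tuple[int, int]:
    """Plane window [start, start+m) with m = ceil(fraction * Z), centered."""
    m = math.ceil(fraction * n_z)
    start = (n_z - m) // 2
    return start, start + m


def center_normalize_array(
    arr: np.ndarray,
    center_fraction: float = 0.5,
    stats_out: dict | None = None,
) -> np.ndarray:
    """z-score a (C, Z, Y, X) volume from middle-Z-chunk statistics."""
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim != 4:
        raise ValueError(
            "center normalization requires a (C, Z, Y, X) volume; "
            f"got rank {arr.ndim}"
        )
    if not 0 < center_fraction <= 1:
        raise ValueError("center_fraction must be in (0, 1]")
    n_z = arr.shape[1]
    if n_z < 2:
        raise ValueError("center normalization requires Z extent >= 2")
    z0, z1 = center_chunk_bounds(n_z, center_fraction)
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        chunk = arr[c, z0:z1]
        mu = float(chunk.mean())
        sd = float(chunk.std())
        if sd == 0:
            raise DegenerateIntensityError(
                f"channel {c}: center chunk (planes {z0}:{z1}) has zero std"
            )
        out[c] = (arr[c] - mu) / sd
        if stats_out is not None:
            stats_out[c] = {"method": "center", "mu": mu, "sd": sd}
    return out


def minmax_normalize_array(
    arr: np.ndarray, out_range: tuple[float, float] = (0.0, 1.0),
    stats_out: dict | None = None,
) -> np.ndarray:
    return percentile_normalize_array(
        arr, lo=0.0, hi=100.0, out_range=out_range, stats_out=stats_out
    )


def un_normalize_array(arr: np.ndarray, stats: dict) -> np.ndarray:
    """Invert a recorded normalization (affine methods exactly; z-score methods
    via the stored per-image statistics)."""
    out = np.empty_like(arr, dtype=np.float32)
    for c in range(arr.shape[0]):
        s = stats[c]
        if s["method"] == "percentile":
            out[c] = (arr[c] - s["a"]) / (s["b"] - s["a"]) * (
                s["p_hi"] - s["p_lo"]
            ) + s["p_lo"]
        else:
            out[c] = arr[c] * s["sd"] + s["mu"]
    return out


# -- NDImage wrappers ----------------------------------------------------

def _wrap(img: NDImage, fn, *args, **kwargs) -> NDImage:
    img = img.canonicalize()
    data = img.data
    had_c = "C" in img.axes.labels
    if not had_c:
        data = data[None]
    out = fn(data.astype(np.float32), *args, **kwargs)
    if not had_c:
        out = out[0]
    return img.with_data(out)


def percentile_normalize(img: NDImage, lo=0.5, hi=99.5, out_range=(-1.0, 1.0)) -> NDImage:
    return _wrap(img, percentile_normalize_array, lo, hi, out_range)


def standard_normalize(img: NDImage) -> NDImage:
    return _wrap(img, standard_normalize_array)


def center_normalize(img: NDImage, center_fraction: float = 0.5) -> NDImage:
    if "Z" not in img.axes.labels:
        raise ValueError("center normalization requires a Z axis")
    return _wrap(img, center_normalize_array, center_fraction)


# ---------------------------------------------------------------------------
# stain normalization (Reinhard statistics transfer in CIELAB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainReference:
    """Per-channel mean and std of a reference tile in CIELAB."""

    means: tuple[float, float, float]
    stds: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.stds):
            raise ValueError("stain reference scales must be > 0")


def _to_rgb01(tile: np.ndarray) -> tuple[np.ndarray, bool]:
    tile = np.asarray(tile)
    if tile.ndim != 3 or 3 not in (tile.shape[0], tile.shape[-1]):
        raise ValueError(f"expected a 3-channel RGB tile, got shape {tile.shape}")
    channels_first = tile.shape[0] == 3 and tile.shape[-1] != 3
    if channels_first:
        tile = np.moveaxis(tile, 0, -1)
    scaled = tile.max() > 1.5
    rgb = tile.astype(np.float64) / (255.0 if scaled else 1.0)
    return np.clip(rgb, 0, 1), channels_first


def fit_stain_reference(ref_tile) -> StainReference:
    """Color statistics of a reference H&E tile, for later transfer."""
    if isinstance(ref_tile, NDImage):
        ref_tile = ref_tile.data
    rgb, _ = _to_rgb01(ref_tile)
    lab = rgb2lab(rgb)
    means = tuple(float(lab[..., i].mean()) for i in range(3))
    stds = tuple(max(float(lab[..., i].std()), 1e-8) for i in range(3))
    return StainReference(means, stds)


def apply_stain_norm(tile, ref: StainReference):
    """Map a tile's CIELAB channel statistics onto the reference's."""
    was_ndimage = isinstance(tile, NDImage)
    arr = tile.data if was_ndimage else np.asarray(tile)
    rgb, channels_first = _to_rgb01(arr)
    scaled = np.asarray(arr).max() > 1.5
    lab = rgb2lab(rgb)
    for i in range(3):
        mu = lab[..., i].mean()
        sd = max(lab[..., i].std(), 1e-8)
        lab[..., i] = (lab[..., i] - mu) / sd * ref.stds[i] + ref.means[i]
    out = np.clip(lab2rgb(lab), 0, 1)
    if scaled:
        out = out * 255.0
    out = out.astype(np.float32)
    if channels_first:
        out = np.moveaxis(out, -1, 0)
    if was_ndimage:
        return tile.with_data(out)
    return out


# ---------------------------------------------------------------------------
# padding to network-valid extents
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropRecord:
    """Inverse of a pad: original spatial extents to crop back to."""

    original_shape: tuple[int, ...]

    def crop(self, arr: np.ndarray) -> np.ndarray:
        sl = tuple(slice(0, s) for s in self.original_shape)
        return arr[(...,) + sl] if arr.ndim > len(self.original_shape) else arr[sl]


def pad_to_valid(
    arr: np.ndarray, factors: tuple[int, ...]
) -> tuple[np.ndarray, CropRecord]:
    """Reflect-pad trailing spatial axes up to multiples of the down factors."""
    spatial = arr.shape[-len(factors):]
    target = tuple(-(-s // f) * f for s, f in zip(spatial, factors))
    pad = [(0, 0)] * (arr.ndim - len(factors)) + [
        (0, t - s) for s, t in zip(spatial, target)
    ]
    if all(p == (0, 0) for p in pad):
        return arr, CropRecord(spatial)
    return np.pad(arr, pad, mode="reflect"), CropRecord(spatial)


# ---------------------------------------------------------------------------
# transform registry (cache-eligible deterministic transforms)
# ---------------------------------------------------------------------------

def apply_transform(name: str, params: dict, arr: np.ndarray) -> np.ndarray:
    """Realize a named deterministic transform on a (C, *spatial) array."""
    if name == "percentile_normalize":
        return percentile_normalize_array(
            arr,
            lo=params.get("lo", 0.5),
            hi=params.get("hi", 99.5),
            out_range=tuple(params.get("out_range", (-1.0, 1.0))),
        )
    if name == "standard_normalize":
        return standard_normalize_array(arr)
    if name == "center_normalize":
        return center_normalize_array(
            arr, center_fraction=params.get("center_fraction", 0.5)
        )
    if name == "minmax_normalize":
        return minmax_normalize_array(
            arr, out_range=tuple(params.get("out_range", (0.0, 1.0)))
        )
    if name == "stain_normalize":
        ref = StainReference(
            tuple(params["ref_means"]), tuple(params["ref_stds"])
        )
        return apply_stain_norm(arr, ref)
    if name == "identity":
        return arr
    raise ValueError(f"unknown transform {name!r}")


# on-the-fly augmentations, applied after patch extraction with a child RNG

def augment_flips_rot90(
    arrays: list[np.ndarray | None], rng: np.random.Generator
) -> list[np.ndarray | None]:
    """Random flips and YX 90-degree rotations, identical across all arrays."""
    d = next(a.ndim for a in arrays if a is not None)
    flips = [rng.random() < 0.5 for _ in range(2)]
    k = int(rng.integers(0, 4))
    out = []
    for a in arrays:
        if a is None:
            out.append(None)
            continue
        for off, do in zip((2, 1), flips):  # X then Y (trailing axes)
            if do:
                a = np.flip(a, axis=a.ndim - off)
        if a.shape[a.ndim - 2] == a.shape[a.ndim - 1]:
            a = np.rot90(a, k, axes=(a.ndim - 2, a.ndim - 1))
        out.append(np.ascontiguousarray(a))
    return out
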