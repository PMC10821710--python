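"""Patch extraction for training.

Patches never cross image boundaries: origins are drawn from the valid-origin
set after padding, so no synthetic zero borders ever enter a loss. Source,
target, exclusion and weight arrays are cropped with the identical window.

Weighted sampling: with probability ``fg_ratio`` the patch is centered on a
positive voxel of the weight map (or, absent one, on target foreground), which
counteracts the background/foreground imbalance of uniform sampling without
resorting to precropped instance-centered datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core.config import PatchSpec
from .io_data.cache import LoadedPair
from .nn import Tensor

log = logging.getLogger(__name__)


@dataclass
class Patch:
    source: np.ndarray  # (C, *patch)
    target: np.ndarray | None
    exclusion: np.ndarray | None  # (*patch,), 1 = excluded
    weight: np.ndarray | None
    origin: tuple[int, ...]


class SamplingError(ValueError):
    pass


def _crop(arr: np.ndarray | None, origin, size, has_channel: bool):
    if arr is None:
        return None
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return arr[(slice(None),) + sl] if has_channel else arr[sl]


def sample_patches(
    pair: LoadedPair, spec: PatchSpec, rng: np.random.Generator
) -> list[Patch]:
    """Draw ``spec.patches_per_image`` congruent crops from a loaded record."""
    spatial = pair.source.shape[1:]
    size = tuple(spec.patch_size)
    if len(size) != len(spatial):
        raise SamplingError(
            f"patch rank {len(size)} != image spatial rank {len(spatial)}"
        )
    if any(p > s for p, s in zip(size, spatial)):
        raise SamplingError(
            f"patch size {size} exceeds image spatial extent {spatial}"
        )
    if pair.target is not None and pair.target.shape[1:] != spatial:
        raise SamplingError("source and target are not spatially congruent")

    max_origin = tuple(s - p for s, p in zip(spatial, size))

    fg_coords = None
    if spec.weighting == "foreground_weighted":
        fg_map = pair.weight
        if fg_map is None and pair.target is not None:
            fg_map = (pair.target[0] > 0).astype(np.float32)
        if fg_map is not None:
            fg_coords = np.argwhere(fg_map > 0)
        if fg_coords is None or len(fg_coords) == 0:
            log.warning(
                "foreground_weighted sampling for %s: weight map is empty; "
                "falling back to uniform",
                pair.record_id,
            )
            fg_coords = None

    patches: list[Patch] = []
    for _ in range(spec.patches_per_image):
        for _attempt in range(10):
            if fg_coords is not None and rng.random() < spec.fg_ratio:
                center = fg_coords[rng.integers(len(fg_coords))]
                origin = tuple(
                    int(np.clip(c - p // 2, 0, m))
                    for c, p, m in zip(center, size, max_origin)
                )
            else:
                origin = tuple(int(rng.integers(0, m + 1)) for m in max_origin)
            excl = _crop(pair.exclusion, origin, size, has_channel=False)
            if excl is not None and excl.min() > 0:
                continue  # fully excluded window: resample
            break
        patches.append(
            Patch(
                source=_crop(pair.source, origin, size, True),
                target=_crop(pair.target, origin, size, True),
                exclusion=excl,
                weight=_crop(pair.weight, origin, size, False),
                origin=origin,
            )
        )
    return patches


def assemble_batch(patches: list[Patch]):
    """Stack patches into (N, C, *spatial) arrays (None where absent)."""
    src = np.stack([p.source for p in patches])
    tgt = (
        np.stack([p.target for p in patches])
        if patches[0].target is not None
        else None
    )
    excl = (
        np.stack([p.exclusion for p in patches])
        if patches[0].exclusion is not None
        else None
    )
    return src, tgt, excl


def apply_exclusion(loss_map: Tensor, mask: np.ndarray | None) -> Tensor:
    """Mean of a per-voxel loss over non-excluded voxels.

    ``mask`` is binary with 1 = excluded; broadcastable to ``loss_map``. The
    gradient with respect to predictions at excluded voxels is identically
    zero because they are multiplied out before the reduction.
    """
    if mask is None:
        return loss_map.mean()
    keep = 1.0 - np.asarray(mask, dtype=np.float32)
    keep = np.broadcast_to(
        keep.reshape(keep.shape[:1] + (1,) + keep.shape[1:])
        if keep.ndim == loss_map.ndim - 1
        else keep,
        loss_map.shape,
    )
    n_keep = float(keep.sum())
    if n_keep == 0:
        raise SamplingError(
            "exclusion mask covers the whole patch: no supervised signal; "
            "resample the patch"
        )
    return (loss_map * keep).sum() * (1.0 / n_keep)
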