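"""Deterministic-transform caching and the dataset handle used for training.

Loading a large microscopy volume and normalizing or padding it is expensive
and, for deterministic transforms, identical in every epoch. The first pass
over a record therefore applies the deterministic prefix of the transform list
and persists the arrays, keyed by a content digest of (file path, file mtime,
serialized transform spec). Later passes load from disk; changing any transform
parameter changes the digest and forces recomputation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..core.axes import NDImage
from ..core.config import TransformSpec
from ..core.records import SamplePair
from .io import read_image
from .manifest import Manifest


class CacheError(IOError):
    pass


def transform_digest(path: Path, transforms: list[TransformSpec], role: str = "") -> str:
    spec_blob = json.dumps(
        [
            {"name": t.name, "params": t.params, "apply_to": t.apply_to}
            for t in transforms
        ],
        sort_keys=True,
    )
    mtime = path.stat().st_mtime_ns if path.exists() else 0
    key = f"{path.resolve()}|{mtime}|{role}|{spec_blob}"
    return hashlib.sha256(key.encode()).hexdigest()[:24]


@dataclass
class LoadedPair:
    """A training record with pixels in memory, deterministic transforms applied."""

    source: np.ndarray  # (C, *spatial) float32
    target: np.ndarray | None
    exclusion: np.ndarray | None
    weight: np.ndarray | None
    record_id: str


def _as_channel_spatial(img: NDImage) -> np.ndarray:
    """Collapse to (C, *spatial); a missing C axis becomes a singleton."""
    img = img.canonicalize()
    data = img.data
    labels = img.axes.labels
    if "T" in labels:
        raise ValueError("training records must be single-timepoint images")
    if "C" not in labels:
        data = data[None]
    return np.ascontiguousarray(data)


class CachedDataset:
    """Applies deterministic transforms once per (record, spec) and caches them.

    ``transform_fn(name, params, array) -> array`` realizes each transform; the
    registry lives in :mod:`im2im.preprocess`. Only transforms flagged
    deterministic may be cached; a non-deterministic entry in the list is a
    caller error.
    """

    def __init__(
        self,
        manifest: Manifest,
        transforms: list[TransformSpec],
        cache_dir: str | Path | None,
        transform_fn,
        split: str = "train",
    ):
        for t in transforms:
            if not t.deterministic:
                raise CacheError(
                    f"transform {t.name!r} is not deterministic; apply it "
                    "after patch extraction, not in the cached pipeline"
                )
        self.records = [r for r in manifest.records if r.split == split]
        self.transforms = transforms
        self.transform_fn = transform_fn
        self.cache_dir = Path(cache_dir) if cache_dir else None
        if self.cache_dir is not None:
            try:
                self.cache_dir.mkdir(parents=True, exist_ok=True)
                probe = self.cache_dir / ".write_probe"
                probe.touch()
                probe.unlink()
            except OSError as err:
                raise CacheError(
                    f"cache_dir {self.cache_dir} not writable: {err}"
                ) from None

    def __len__(self):
        return len(self.records)

    def _prepare_image(self, path: Path, is_source: bool) -> np.ndarray:
        arr = _as_channel_spatial(read_image(path))
        arr = arr.astype(np.float32)
        role = "source" if is_source else "target"
        for t in self.transforms:
            if t.apply_to in ("both", role):
                arr = self.transform_fn(t.name, t.params, arr)
        return arr

    def _cached_array(self, path: Path, is_source: bool) -> np.ndarray:
        if self.cache_dir is None:
            return self._prepare_image(path, is_source)
        digest = transform_digest(
            path, self.transforms, "source" if is_source else "target"
        )
        cache_file = self.cache_dir / f"{path.stem}-{digest}.npy"
        if cache_file.exists():
            return np.load(cache_file)
        arr = self._prepare_image(path, is_source)
        np.save(cache_file, arr)
        return arr

    def load(self, idx: int) -> LoadedPair:
        rec: SamplePair = self.records[idx]
        source = np.concatenate(
            [self._cached_array(p, True) for p in rec.source], axis=0
        )
        target = None
        if rec.target:
            target = np.concatenate(
                [self._cached_array(p, False) for p in rec.target], axis=0
            )
        exclusion = None
        if rec.exclusion_mask is not None:
            excl_img = _as_channel_spatial(read_image(rec.exclusion_mask))
            exclusion = (excl_img[0] > 0).astype(np.float32)
            if target is not None and exclusion.shape != target.shape[1:]:
                raise CacheError(
                    f"exclusion mask shape {exclusion.shape} does not match "
                    f"target spatial shape {target.shape[1:]} for record "
                    f"{rec.record_id}"
                )
        weight = None
        if rec.weight_map is not None:
            weight = _as_channel_spatial(read_image(rec.weight_map))[0].astype(
                np.float32
            )
        return LoadedPair(source, target, exclusion, weight, rec.record_id)


def cached_dataset(
    manifest: Manifest,
    deterministic_transforms: list[TransformSpec],
    cache_dir: str | Path | None,
    transform_fn,
    split: str = "train",
) -> CachedDataset:
    return CachedDataset(
        manifest, deterministic_transforms, cache_dir, transform_fn, split
    )
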