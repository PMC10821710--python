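"""Building training manifests from the four supported data layouts.

Modes
-----
csv_manifest
    One record per CSV row; columns named by ``source_key`` / ``target_key``
    plus optional ``exclusion_path`` / ``weight_path`` columns.
paired_folders
    Two sibling folders (default ``image`` and ``ground_truth`` named by the
    keys); records matched by identical filename.
suffix_convention
    One folder of ``stem_IM.tif`` / ``stem_GT.tif`` files (suffixes
    configurable) matched by stem; optional ``stem_EM.tif`` exclusion masks.
presplit_folders
    ``train/`` and ``val/`` subtrees, each in paired_folders layout; the
    subtree assigns the split directly.

Record order is deterministic (lexicographic by source path); the random
train/val split is driven by the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ..core.config import DataConfig
from ..core.records import SamplePair
from ..core.seeding import SeedTree

_IMG_EXTS = (".tif", ".tiff", ".ome.tif", ".ome.tiff")


class ManifestError(ValueError):
    pass


@dataclass
class Manifest:
    records: list[SamplePair]
    mode: str
    root: Path
    provenance: dict = field(default_factory=dict)

    @property
    def train(self) -> list[SamplePair]:
        return [r for r in self.records if r.split == "train"]

    @property
    def val(self) -> list[SamplePair]:
        return [r for r in self.records if r.split == "val"]

    def __len__(self):
        return len(self.records)


def _is_image(p: Path) -> bool:
    return p.suffix.lower() in (".tif", ".tiff")


def _list_images(folder: Path) -> list[Path]:
    return sorted(p for p in folder.iterdir() if p.is_file() and _is_image(p))


def _check_exists(path: Path, what: str):
    if not path.exists():
        raise ManifestError(f"{what} does not exist: {path}")


def _from_csv(cfg: DataConfig, root: Path) -> list[SamplePair]:
    csv_path = root if root.suffix == ".csv" else root / "manifest.csv"
    _check_exists(csv_path, "CSV manifest")
    df = pd.read_csv(csv_path)
    for col in (cfg.source_key, cfg.target_key):
        if col not in df.columns:
            raise ManifestError(f"CSV {csv_path} lacks required column {col!r}")
    base = csv_path.parent
    records = []
    for i, row in df.iterrows():
        src = base / str(row[cfg.source_key])
        tgt = base / str(row[cfg.target_key])
        for p, what in ((src, "source"), (tgt, "target")):
            if not p.exists():
                raise ManifestError(f"CSV row {i}: {what} file missing: {p}")
        excl = None
        ecol = cfg.exclusion_key or "exclusion_path"
        if ecol in df.columns and pd.notna(row[ecol]):
            excl = base / str(row[ecol])
            if not excl.exists():
                raise ManifestError(f"CSV row {i}: exclusion file missing: {excl}")
        wmap = None
        wcol = cfg.weight_key or "weight_path"
        if wcol in df.columns and pd.notna(row[wcol]):
            wmap = base / str(row[wcol])
            if not wmap.exists():
                raise ManifestError(f"CSV row {i}: weight file missing: {wmap}")
        records.append(
            SamplePair([src], [tgt], exclusion_mask=excl, weight_map=wmap)
        )
    return records


def _pair_folders(src_dir: Path, tgt_dir: Path) -> list[SamplePair]:
    _check_exists(src_dir, "source folder")
    _check_exists(tgt_dir, "target folder")
    src_files = {p.name: p for p in _list_images(src_dir)}
    tgt_files = {p.name: p for p in _list_images(tgt_dir)}
    orphans = sorted(set(src_files) ^ set(tgt_files))
    if orphans:
        raise ManifestError(
            f"unmatched files between {src_dir.name}/ and {tgt_dir.name}/: {orphans}"
        )
    return [
        SamplePair([src_files[n]], [tgt_files[n]]) for n in sorted(src_files)
    ]


def _from_suffix(cfg: DataConfig, root: Path) -> list[SamplePair]:
    _check_exists(root, "data folder")
    files = _list_images(root)
    sources, targets, excls = {}, {}, {}
    for p in files:
        stem = p.stem
        if stem.endswith(cfg.source_suffix):
            sources[stem[: -len(cfg.source_suffix)]] = p
        elif stem.endswith(cfg.target_suffix):
            targets[stem[: -len(cfg.target_suffix)]] = p
        elif stem.endswith(cfg.exclusion_suffix):
            excls[stem[: -len(cfg.exclusion_suffix)]] = p
    orphans = sorted(set(sources) ^ set(targets))
    if orphans:
        raise ManifestError(f"orphan stems without a matching pair: {orphans}")
    return [
        SamplePair([sources[s]], [targets[s]], exclusion_mask=excls.get(s))
        for s in sorted(sources)
    ]


def _assign_split(records: list[SamplePair], val_fraction: float, seeds: SeedTree):
    n = len(records)
    n_val = int(round(val_fraction * n))
    if n - n_val < 1:
        raise ManifestError(
            f"val_fraction={val_fraction} leaves no training records (n={n})"
        )
    rng = seeds.child("io_data.split")
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    for i, r in enumerate(records):
        r.split = "val" if i in val_idx else "train"


def build_manifest(cfg: DataConfig, seeds: SeedTree | None = None) -> Manifest:
    """Scan the configured layout into a deterministic, validated manifest."""
    root = Path(cfg.data_path)
    seeds = seeds or SeedTree()
    if cfg.mode == "csv_manifest":
        records = _from_csv(cfg, root)
    elif cfg.mode == "paired_folders":
        records = _pair_folders(root / cfg.source_key, root / cfg.target_key)
    elif cfg.mode == "suffix_convention":
        records = _from_suffix(cfg, root)
    elif cfg.mode == "presplit_folders":
        records = []
        for split in ("train", "val"):
            sub = root / split
            if not sub.exists():
                if split == "val":
                    continue
                raise ManifestError(f"presplit_folders layout lacks {sub}")
            for r in _pair_folders(sub / cfg.source_key, sub / cfg.target_key):
                r.split = split
                records.append(r)
    else:  # pragma: no cover - schema forbids
        raise ManifestError(f"unknown mode {cfg.mode!r}")

    if not records:
        raise ManifestError(f"empty manifest for {cfg.mode} at {root}")
    records.sort(key=lambda r: str(r.source[0]))
    if cfg.mode != "presplit_folders":
        _assign_split(records, cfg.val_fraction, seeds)
    return Manifest(
        records=records,
        mode=cfg.mode,
        root=root,
        provenance={"mode": cfg.mode, "root": str(root)},
    )
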