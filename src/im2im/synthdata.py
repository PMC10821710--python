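"""Seeded desk-scale fixture generation for every framework.

Worlds are collections of non-overlapping random ellipses (2D) or ellipsoids
(3D) — "nuclei" — with per-object amplitudes and a smooth interior texture,
rendered through a Gaussian PSF onto a noisy background, with the exact
instance labels kept alongside. From one world the task modes derive paired
records:

* ``labelfree``  — source: inverted, edge-enhanced, heavily blurred rendering
  (a brightfield-like nonlinear transform; hard enough that an identity model
  fails), target: the clean fluorescence-like intensity.
* ``semantic``   — target: binarized labels.
* ``instance``   — target: integer instance map, plus an exclusion mask that is
  exactly the union of instances touching an image border (uncurated
  border-touching objects are the standard reason for exclusion masks).
* ``denoise``    — source: low-SNR rendering; target: high-SNR rendering of the
  same world.
* ``stain``      — H&E-like RGB tiles via two simulated stain vectors with
  per-image color jitter.
* ``modality``   — source: heavily blurred rendering; target: lightly blurred.

The defaults define the package's reference test conditions: 64×64 (2D) or
8×32×32 (3D) canvases, 2–6 objects, Gaussian read noise σ=0.05 of signal
range, PSF σ=1 px. Every generated source has an exactly known target, so
metric ceilings (Pearson 1.0 against the stored target) are available for
free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .core.axes import NDImage
from .io_data.io import write_image

TASKS = ("labelfree", "semantic", "instance", "denoise", "stain", "modality")


@dataclass
class FixtureSpec:
    task: str = "labelfree"
    dim: int = 2
    shape: tuple[int, ...] = ()
    n_objects: tuple[int, int] = (2, 6)
    noise_sigma: float = 0.05
    poisson_scale: float = 0.0
    psf_sigma: float = 1.0
    seed: int = 42
    n_images: int = 6

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")
        if not self.shape:
            self.shape = (64, 64) if self.dim == 2 else (8, 32, 32)
        self.shape = tuple(int(s) for s in self.shape)
        mins = (16, 16) if self.dim == 2 else (8, 16, 16)
        if any(s < m for s, m in zip(self.shape, mins)):
            raise ValueError(f"shape {self.shape} below minimum {mins}")


@dataclass
class BlobWorld:
    instances: np.ndarray  # integer labels
    intensity: np.ndarray  # clean, in [0, 1]
    n_placed: int


def _ellipse_mask(shape, center, radii, rng) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def make_blob_world(spec: FixtureSpec, rng: np.random.Generator) -> BlobWorld:
    """Place non-overlapping ellipses/ellipsoids; render intensity with texture,
    PSF blur, background and noise. Returns exact labels alongside."""
    shape = spec.shape
    n_req = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
    labels = np.zeros(shape, dtype=np.int32)
    intensity = np.zeros(shape, dtype=np.float64)
    placed = 0
    base_r = max(3.0, min(shape[-2:]) / 8.0)
    for _ in range(n_req):
        ok = False
        for _attempt in range(100):
            radii = []
            for a, s in enumerate(shape):
                r = base_r * rng.uniform(0.7, 1.3)
                if spec.dim == 3 and a == 0:  # flatter along Z (anisotropy)
                    r = max(1.5, r * shape[0] / shape[-1])
                radii.append(min(r, s / 2.5))
            center = [rng.uniform(r, s - r) for r, s in zip(radii, shape)]
            mask = _ellipse_mask(shape, center, radii, rng)
            if mask.sum() < 4 or (labels[mask] > 0).any():
                continue
            placed += 1
            labels[mask] = placed
            amp = rng.uniform(0.5, 1.0)
            texture = gaussian_filter(
                rng.standard_normal(shape), sigma=2.0
            )
            texture = 1.0 + 0.25 * texture / max(np.abs(texture).max(), 1e-8)
            intensity[mask] = amp * texture[mask]
            ok = True
            break
        if not ok:
            break
    clean = gaussian_filter(intensity, sigma=spec.psf_sigma) + 0.1
    clean = np.clip(clean, 0, None)
    return BlobWorld(labels, clean.astype(np.float32), placed)


def _add_noise(img: np.ndarray, spec: FixtureSpec, rng, sigma=None) -> np.ndarray:
    sigma = spec.noise_sigma if sigma is None else sigma
    out = img.astype(np.float64)
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
    out = out + rng.normal(0, sigma, img.shape)
    return out.astype(np.float32)


def _brightfield_like(clean: np.ndarray, rng, spec: FixtureSpec) -> np.ndarray:
    """Inverted, edge-enhanced, heavily blurred rendering of the world."""
    blurred = gaussian_filter(clean.astype(np.float64), sigma=2.5)
    grads = np.gradient(gaussian_filter(clean.astype(np.float64), sigma=1.0))
    edges = np.sqrt(sum(g**2 for g in grads))
    bf = 1.0 - blurred + 1.5 * edges
    return _add_noise(bf.astype(np.float32), spec, rng)


def _border_touch_mask(labels: np.ndarray) -> np.ndarray:
    """Union of instances touching any image edge (binary, 1 = excluded)."""
    touching = set()
    for a in range(labels.ndim):
        for sl in (0, -1):
            idx = [slice(None)] * labels.ndim
            idx[a] = sl
            touching |= set(int(v) for v in np.unique(labels[tuple(idx)]) if v > 0)
    out = np.isin(labels, sorted(touching))
    return out.astype(np.uint8)


def _stain_tile(world: BlobWorld, rng) -> np.ndarray:
    """H&E-like RGB tile: two stain vectors + per-image color jitter."""
    h_conc = (world.instances > 0).astype(np.float64)  # nuclei: hematoxylin
    h_conc = gaussian_filter(h_conc, 1.0)
    e_conc = gaussian_filter((world.intensity > 0.12).astype(np.float64), 2.0) * 0.6
    stain_h = np.array([0.65, 0.70, 0.29]) * rng.uniform(0.85, 1.15, 3)
    stain_e = np.array([0.07, 0.99, 0.11]) * rng.uniform(0.85, 1.15, 3)
    od = h_conc[..., None] * stain_h + e_conc[..., None] * stain_e
    rgb = np.exp(-od)  # Beer-Lambert
    rgb = np.clip(rgb + rng.normal(0, 0.01, rgb.shape), 0, 1)
    return np.moveaxis((rgb * 255).astype(np.uint8), -1, 0)  # (3, Y, X)


def render_pair(
    world: BlobWorld, spec: FixtureSpec, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(source, target, exclusion) arrays for the spec's task."""
    if spec.task == "labelfree":
        return _brightfield_like(world.intensity, rng, spec), world.intensity, None
    if spec.task == "semantic":
        src = _add_noise(world.intensity, spec, rng)
        return src, (world.instances > 0).astype(np.uint16), None
    if spec.task == "instance":
        src = _add_noise(world.intensity, spec, rng)
        return src, world.instances.astype(np.uint16), _border_touch_mask(world.instances)
    if spec.task == "denoise":
        low = _add_noise(world.intensity, spec, rng, sigma=spec.noise_sigma * 6)
        high = _add_noise(world.intensity, spec, rng, sigma=spec.noise_sigma * 0.5)
        return low, high, None
    if spec.task == "modality":
        src = _add_noise(
            gaussian_filter(world.intensity.astype(np.float64), 3.0).astype(np.float32),
            spec, rng,
        )
        tgt = gaussian_filter(world.intensity.astype(np.float64), 0.5).astype(np.float32)
        return src, tgt, None
    if spec.task == "stain":
        tile = _stain_tile(world, rng)
        return tile, (world.instances > 0).astype(np.uint16), None
    raise ValueError(spec.task)


def _axes_for(arr: np.ndarray, dim: int) -> str:
    if arr.ndim == dim + 1:
        return "C" + ("ZYX" if dim == 3 else "YX")
    return "ZYX" if dim == 3 else "YX"


def make_task_pairs(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a fixture dataset: TIFFs + CSV manifest + the generating spec.

    Returns the path to the CSV manifest, loadable via
    ``io_data.build_manifest`` in csv_manifest mode (and laid out to also work
    in paired-folder modes).
    """
    out = Path(out_dir)
    (out / "image").mkdir(parents=True, exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    (out / "exclusion").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    # voxel calibration matching 100x light microscopy acquisitions
    voxel = (0.29, 0.108, 0.108) if spec.dim == 3 else (0.108, 0.108)
    for i in range(spec.n_images):
        world = make_blob_world(spec, rng)
        source, target, excl = render_pair(world, spec, rng)
        name = f"img_{i:03d}.tif"
        src_path = out / "image" / name
        tgt_path = out / "ground_truth" / name
        write_image(
            NDImage(source, _axes_for(source, spec.dim), voxel_size=voxel), src_path
        )
        write_image(
            NDImage(target, _axes_for(target, spec.dim), voxel_size=voxel), tgt_path
        )
        row = {
            "source_path": str(src_path.relative_to(out)),
            "target_path": str(tgt_path.relative_to(out)),
        }
        if excl is not None:
            excl_path = out / "exclusion" / name
            write_image(NDImage(excl, _axes_for(excl, spec.dim)), excl_path)
            row["exclusion_path"] = str(excl_path.relative_to(out))
        rows.append(row)
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    with open(out / "fixture_spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "task": spec.task, "dim": spec.dim, "shape": list(spec.shape),
                "n_objects": list(spec.n_objects), "noise_sigma": spec.noise_sigma,
                "poisson_scale": spec.poisson_scale, "psf_sigma": spec.psf_sigma,
                "seed": spec.seed, "n_images": spec.n_images,
            },
            fh,
        )
    return manifest_path
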