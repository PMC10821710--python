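"""Embedding-based instance segmentation (EmbedSeg-type).

The network predicts, per pixel, a spatial offset vector, a clustering
bandwidth (sigma) and a seediness score. Training pulls each foreground
pixel's embedding ``e_i = x_i + o_i`` (``x_i`` the pixel's normalized
coordinate, ``o_i`` the tanh-limited predicted offset) toward its instance
center ``C_k`` through a Gaussian kernel

    phi_k(e_i) = exp(-||e_i - C_k||^2 / (2 sigma_k^2)),

where ``sigma_k`` is the mean predicted sigma over instance ``k`` (optionally
per axis for anisotropic data). The loss has three terms: a binary
cross-entropy of ``phi_k`` against instance membership evaluated over the
instance plus nearby background (its bounding box dilated by ``bg_margin``),
a sigma-smoothness term (variance of sigma within the instance), and a seed
regression term pulling the seed map toward ``phi_k`` on foreground and 0 on
background. All terms honour an exclusion mask, so partially annotated images
train cleanly.

Centers are computed on the fly from the cropped patch (medoid by default —
guaranteed to lie inside non-convex instances), so augmentation never
invalidates them. Decoding clusters pixels greedily around the
highest-seediness candidates; because assignment is by embedding distance
only, an instance may consist of several disconnected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core.config import EmbedSegParams, FrameworkConfig, NetworkSpec, TrainerConfig
from .core.resolve import resolve_network
from .metrics import average_precision
from .nn import Adam, Tensor

_F32 = np.float32


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@dataclass
class InstanceTarget:
    """Per-patch instance labels with per-instance centers in normalized coords."""

    instances: np.ndarray  # integer label map, 0 = background
    centers: dict[int, np.ndarray] = field(default_factory=dict)
    exclusion: np.ndarray | None = None


def normalized_grid(shape: tuple[int, ...]) -> np.ndarray:
    """(d, *shape) array of per-axis pixel coordinates scaled to [0, 1)."""
    axes = [np.arange(s, dtype=_F32) / s for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack(mesh).astype(_F32)


def compute_centers(
    instances: np.ndarray, mode: str = "medoid", exclusion: np.ndarray | None = None
) -> InstanceTarget:
    """Per-instance center coordinates (normalized), computed per patch.

    centroid: mean coordinate of the instance's voxels (may fall outside a
    non-convex instance). medoid: the instance voxel minimizing the summed
    distance to all its voxels; ties break to the lexicographically lowest
    voxel.
    """
    instances = np.asarray(instances)
    shape = instances.shape
    scale = np.array(shape, dtype=np.float64)
    target = InstanceTarget(instances=instances, exclusion=exclusion)
    for label in np.unique(instances):
        if label <= 0:
            continue
        coords = np.argwhere(instances == label)  # lexicographic order
        if mode == "centroid":
            center = coords.mean(axis=0)
        elif mode == "medoid":
            if len(coords) > 4096:
                # subsampled distance sums are a faithful approximation at
                # this size and keep target prep linear-ish
                ref = coords[:: max(1, len(coords) // 2048)]
            else:
                ref = coords
            d = ((coords[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
            sums = np.sqrt(d).sum(axis=1)
            center = coords[int(np.argmin(sums))]
        else:
            raise ValueError(f"unknown center mode {mode!r}")
        target.centers[int(label)] = (center / scale).astype(_F32)
    return target


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

# Baseline clustering bandwidth in normalized coordinates: sigma =
# exp(raw + ln SIGMA_BASELINE). At 1.0 an untrained network starts with an
# image-scale kernel, so every instance pixel receives a useful pull from the
# first step; the bandwidth then contracts to object scale as offsets
# converge. (Starting at object scale stalls: distant pixels begin with
# vanishing phi and the background term dominates.)
SIGMA_BASELINE = 1.0

# Gain on the raw seed head before the sigmoid. Adaptive-moment optimizers
# move each parameter by roughly lr per step, so within a short training
# budget a unit-gain sigmoid cannot reach the saturated values (>0.9) the
# decoder keys on; the gain rescales the head to the optimizer's step size.
SEED_GAIN = 5.0


def split_heads(pred: Tensor, d: int, per_axis_sigma: bool):
    """Slice raw network output into (offsets tanh, sigma exp, seed sigmoid)."""
    ns = d if per_axis_sigma else 1
    offsets = pred[:, 0:d].tanh()
    sigma = (pred[:, d : d + ns] + float(np.log(SIGMA_BASELINE))).exp()
    seed = (pred[:, d + ns : d + ns + 1] * SEED_GAIN).sigmoid()
    return offsets, sigma, seed


def _bbox_region(mask: np.ndarray, margin: int) -> tuple[slice, ...]:
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def embedseg_loss(
    pred: Tensor,
    targets: list[InstanceTarget],
    params: EmbedSegParams,
) -> Tensor:
    """Total spatial-embedding loss for a batch.

    ``pred``: raw network output (N, d + n_sigma + 1, *spatial);
    ``targets``: one :class:`InstanceTarget` per batch item.
    """
    n = pred.shape[0]
    d = pred.ndim - 2
    spatial = pred.shape[2:]
    grid = normalized_grid(spatial)  # (d, *S)
    offsets, sigma, seed = split_heads(pred, d, params.per_axis_sigma)

    total = Tensor(np.zeros(()))
    eps = 1e-6
    for i in range(n):
        tgt = targets[i]
        keep = None
        if tgt.exclusion is not None:
            keep = tgt.exclusion == 0
        e = offsets[i] + Tensor(grid)  # (d, *S)
        sig = sigma[i]  # (ns, *S)
        sd = seed[i][0]  # (*S)

        labels = [int(v) for v in np.unique(tgt.instances) if v > 0]
        inst_term = Tensor(np.zeros(()))
        var_term = Tensor(np.zeros(()))
        seed_fg = Tensor(np.zeros(()))
        fg_any = np.zeros(spatial, dtype=bool)
        n_terms = 0
        for label in labels:
            mask = tgt.instances == label
            if keep is not None:
                mask = mask & keep
            if not mask.any():
                continue
            fg_any |= mask
            center = tgt.centers[label].reshape(-1, 1)  # (d, 1)
            # instance-mean sigma
            sig_in = sig[(slice(None),) + np.nonzero(mask)]  # (ns, M)
            sigma_k = sig_in.mean(axis=1)  # (ns,)
            # smoothness: variance of sigma inside the instance
            var_term = var_term + ((sig_in - sigma_k.reshape(-1, 1)) ** 2).mean()
            # phi over instance + nearby background
            region = np.zeros(spatial, dtype=bool)
            region[_bbox_region(mask, params.bg_margin)] = True
            if keep is not None:
                region &= keep
            ridx = np.nonzero(region)
            er = e[(slice(None),) + ridx]  # (d, R)
            diff2 = (er - Tensor(center)) ** 2
            if params.per_axis_sigma:
                denom = 2.0 * sigma_k.reshape(-1, 1) ** 2
                expo = (diff2 / denom).sum(axis=0)
            else:
                expo = diff2.sum(axis=0) / (2.0 * sigma_k.reshape(1)[0] ** 2 + eps)
            phi = (-expo).exp()
            y = mask[ridx].astype(_F32)
            # BCE of phi against membership, computed stably: the foreground
            # term -log(phi) is exactly `expo` (differentiable even when phi
            # underflows); only the background term needs a clamp near phi=1.
            # The two sides are balanced (mean over instance pixels plus mean
            # over background pixels) so a small instance in a large window
            # is not drowned out by background.
            bg_term = -((1.0 - phi).clamp(eps, 1.0)).log()
            n_fg = max(float(y.sum()), 1.0)
            n_bg = max(float((1.0 - y).sum()), 1.0)
            inst_term = inst_term + 0.5 * (
                (Tensor(y) * expo).sum() * (1.0 / n_fg)
                + (Tensor(1.0 - y) * bg_term).sum() * (1.0 / n_bg)
            )
            # seed regression toward phi (detached) on the instance pixels
            inmask_in_region = mask[ridx]
            phi_const = phi.data[inmask_in_region]
            sd_in = sd[np.nonzero(mask)]
            # seed regresses toward phi (detached) on the instance's pixels
            seed_fg = seed_fg + ((sd_in - Tensor(phi_const)) ** 2).mean()
            n_terms += 1
        if n_terms > 0:
            inst_term = inst_term * (1.0 / n_terms)
            var_term = var_term * (1.0 / n_terms)
            seed_fg = seed_fg * (1.0 / n_terms)
        # seed background: push toward 0 outside any instance
        bg = ~fg_any
        if keep is not None:
            bg &= keep
        if bg.any():
            sd_bg = sd[np.nonzero(bg)]
            seed_bg = (sd_bg**2).mean()
        else:
            seed_bg = Tensor(np.zeros(()))
        total = total + (
            params.w_instance * inst_term
            + params.w_sigma * var_term
            + params.w_seed * (seed_fg + seed_bg)
        )
    return total * (1.0 / n)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_instances(
    offsets: np.ndarray,
    sigma: np.ndarray,
    seed: np.ndarray,
    fg_threshold: float = 0.5,
    seed_threshold: float = 0.9,
    min_size: int = 2,
    phi_cut: float = 0.5,
) -> np.ndarray:
    """Cluster pixel embeddings into an instance label map.

    Iteratively: take the unassigned candidate (seed > ``fg_threshold``) with
    the highest seediness as a cluster center (its embedding and sigma), then
    absorb every unassigned candidate whose Gaussian affinity to that center
    exceeds ``phi_cut``. New clusters are seeded only while the best remaining
    seediness exceeds ``seed_threshold``; clusters smaller than ``min_size``
    voxels are discarded. Deterministic: ties break by voxel order.
    """
    spatial = seed.shape
    d = offsets.shape[0]
    grid = normalized_grid(spatial)
    e = grid + offsets  # (d, *S)
    flat_e = e.reshape(d, -1)
    flat_sigma = sigma.reshape(sigma.shape[0], -1)
    flat_seed = seed.reshape(-1)

    candidates = flat_seed > fg_threshold
    labels = np.zeros(flat_seed.shape, dtype=np.int32)
    assigned = ~candidates
    next_label = 1
    while True:
        open_idx = np.nonzero(~assigned)[0]
        if len(open_idx) == 0:
            break
        best = open_idx[int(np.argmax(flat_seed[open_idx]))]
        if flat_seed[best] <= seed_threshold:
            break
        center = flat_e[:, best : best + 1]  # (d,1)
        sig = flat_sigma[:, best]  # (ns,)
        diff2 = (flat_e[:, open_idx] - center) ** 2
        if sigma.shape[0] == d:
            expo = (diff2 / (2.0 * sig.reshape(-1, 1) ** 2)).sum(axis=0)
        else:
            expo = diff2.sum(axis=0) / (2.0 * float(sig[0]) ** 2)
        phi = np.exp(-expo)
        members = open_idx[phi > phi_cut]
        if best not in members:
            members = np.append(members, best)
        labels[members] = next_label
        assigned[members] = True
        next_label += 1

    out = labels.reshape(spatial)
    # size filter with relabeling in creation order
    final = np.zeros_like(out)
    nxt = 1
    for lab in range(1, next_label):
        m = out == lab
        if m.sum() >= min_size:
            final[m] = nxt
            nxt += 1
    return final


def decode_from_maps(pred: np.ndarray, params: EmbedSegParams, d: int) -> np.ndarray:
    """Decode from raw (C, *spatial) network output (tanh/exp/sigmoid applied)."""
    ns = d if params.per_axis_sigma else 1
    offsets = np.tanh(pred[0:d])
    sigma = np.exp(pred[d : d + ns] + np.log(SIGMA_BASELINE))
    seed = 1.0 / (1.0 + np.exp(-SEED_GAIN * pred[d + ns]))
    return decode_instances(
        offsets,
        sigma,
        seed,
        fg_threshold=params.fg_threshold,
        seed_threshold=params.seed_threshold,
        min_size=params.min_size,
    )


def merge_tile_instances(
    full: np.ndarray, tile: np.ndarray, origin: tuple[int, ...], iou_merge: float = 0.5
) -> np.ndarray:
    """Merge a decoded tile into a growing instance map.

    Tile instances overlapping an existing instance with IoU >= ``iou_merge``
    adopt its label; others get fresh labels. Used by tiled EmbedSeg inference.
    """
    sl = tuple(slice(o, o + s) for o, s in zip(origin, tile.shape))
    window = full[sl]
    next_label = int(full.max()) + 1
    for lab in np.unique(tile):
        if lab <= 0:
            continue
        m = tile == lab
        overlapping = np.unique(window[m])
        best_lab, best_iou = 0, 0.0
        for ex in overlapping:
            if ex <= 0:
                continue
            ex_mask = window == ex
            inter = np.logical_and(m, ex_mask).sum()
            iou = inter / (m.sum() + ex_mask.sum() - inter)
            if iou > best_iou:
                best_lab, best_iou = int(ex), iou
        if best_iou >= iou_merge:
            window[m & (window == 0)] = best_lab
        else:
            window[m & (window == 0)] = next_label
            next_label += 1
    full[sl] = window
    return full


def embedseg_validate(pred_maps: list[np.ndarray], gt_maps: list[np.ndarray]) -> list[float]:
    """AP at IoU 0.5 per image."""
    return [average_precision(p, g, 0.5) for p, g in zip(pred_maps, gt_maps)]


# ---------------------------------------------------------------------------
# framework driver
# ---------------------------------------------------------------------------

class EmbedSegFramework:
    kind = "embedseg"

    def __init__(self, cfg: FrameworkConfig, net_spec: NetworkSpec,
                 trainer: TrainerConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.params = cfg.embedseg
        d = net_spec.dim
        ns = d if self.params.per_axis_sigma else 1
        needed = d + ns + 1
        if net_spec.out_channels != needed:
            net_spec = net_spec.model_copy(update={"out_channels": needed})
        self.net_spec = net_spec
        self.trainer = trainer
        self.net = resolve_network(net_spec, rng)
        self.opt = Adam(
            self.net.parameters(), lr=trainer.lr_for("generator", 1e-3)
        )

    def networks(self):
        return {"generator": self.net}

    def training_step(self, batch) -> dict[str, float]:
        source, target, excl = batch
        targets = []
        for i in range(target.shape[0]):
            inst = target[i, 0].astype(np.int32)
            targets.append(
                compute_centers(
                    inst,
                    mode=self.params.center_mode,
                    exclusion=excl[i] if excl is not None else None,
                )
            )
        self.opt.zero_grad()
        pred = self.net(Tensor(source))
        loss = embedseg_loss(pred, targets, self.params)
        loss.backward()
        self.opt.step()
        return {"loss": loss.item()}

    def predictor(self):
        net = self.net

        def fn(x: np.ndarray) -> np.ndarray:
            net.eval()
            out = net(Tensor(x)).data
            net.train()
            return out

        return fn

    def decoder(self):
        d = self.net_spec.dim
        params = self.params

        def fn(raw: np.ndarray) -> np.ndarray:
            return decode_from_maps(raw, params, d)[None].astype(np.float32)

        return fn

    def state_dict(self):
        return {"generator": self.net.state_dict()}

    def load_state_dict(self, state):
        self.net.load_state_dict(state["generator"])
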