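"""Evaluation metrics: Pearson, SSIM, PSNR, pixel F1, and AP at IoU 0.5.

Conventions
-----------
* SSIM uses a 7-wide uniform window with the standard stabilizers
  (K1=0.01, K2=0.03); for 3D inputs it is computed per Z plane and averaged
  (a volumetric window is available via ``volumetric=True``).
* AP@50 follows the instance-segmentation community convention
  ``TP / (TP + FP + FN)`` with greedy one-to-one matching by descending IoU.
* Aggregation is reported mean ± population std.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

INF_SENTINEL = float("inf")


def pearson(pred: np.ndarray, gt: np.ndarray) -> float:
    """Sample Pearson correlation over all voxels, flattened."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    g = np.asarray(gt, dtype=np.float64).ravel()
    if p.std() == 0 or g.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(np.corrcoef(p, g)[0, 1])


def ssim(
    pred: np.ndarray,
    gt: np.ndarray,
    data_range: float,
    volumetric: bool = False,
) -> float:
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    kwargs = dict(win_size=7, gaussian_weights=False, K1=0.01, K2=0.03,
                  data_range=data_range)
    if pred.ndim == 3 and not volumetric:
        vals = [
            structural_similarity(pred[z], gt[z], **kwargs)
            for z in range(pred.shape[0])
        ]
        return float(np.mean(vals))
    return float(structural_similarity(pred, gt, **kwargs))


def psnr(pred: np.ndarray, gt: np.ndarray, data_range: float) -> float:
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((np.asarray(pred, np.float64) - np.asarray(gt, np.float64)) ** 2))
    if mse == 0:
        return INF_SENTINEL
    return float(10.0 * np.log10(data_range**2 / mse))


def f1_pixel(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    p = np.asarray(pred_mask) > 0
    g = np.asarray(gt_mask) > 0
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    if tp + fp + fn == 0:
        return 1.0  # both empty
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _instance_ious(pred: np.ndarray, gt: np.ndarray):
    """IoU matrix between positive labels of two instance maps."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    pred_labels = [int(v) for v in np.unique(pred) if v > 0]
    gt_labels = [int(v) for v in np.unique(gt) if v > 0]
    iou = np.zeros((len(pred_labels), len(gt_labels)))
    for i, pl in enumerate(pred_labels):
        pm = pred == pl
        ps = pm.sum()
        for j, gl in enumerate(gt_labels):
            gm = gt == gl
            inter = np.logical_and(pm, gm).sum()
            if inter:
                iou[i, j] = inter / (ps + gm.sum() - inter)
    return iou, pred_labels, gt_labels


def average_precision(
    pred: np.ndarray, gt: np.ndarray, iou_thresh: float = 0.5
) -> float:
    """AP at a single IoU threshold: TP / (TP + FP + FN), greedy matching."""
    iou, pred_labels, gt_labels = _instance_ious(pred, gt)
    n_pred, n_gt = len(pred_labels), len(gt_labels)
    if n_pred == 0 and n_gt == 0:
        return 1.0
    matched_pred: set[int] = set()
    matched_gt: set[int] = set()
    # greedy: repeatedly take the globally largest remaining IoU
    pairs = sorted(
        ((iou[i, j], i, j) for i in range(n_pred) for j in range(n_gt)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    tp = 0
    for v, i, j in pairs:
        if v < iou_thresh:
            break
        if i in matched_pred or j in matched_gt:
            continue
        matched_pred.add(i)
        matched_gt.add(j)
        tp += 1
    fp = n_pred - tp
    fn = n_gt - tp
    return tp / (tp + fp + fn)


@dataclass
class MetricReport:
    """Per-image metric values plus mean ± population-std summary."""

    per_image: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, record_id: str, metric: str, value: float):
        self.per_image.append((record_id, metric, float(value)))

    def values(self, metric: str) -> list[float]:
        return [v for _, m, v in self.per_image if m == metric]

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for metric in sorted({m for _, m, _ in self.per_image}):
            vals = np.array(self.values(metric), dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            if len(finite) == 0:
                out[metric] = (float("inf"), 0.0)
            else:
                out[metric] = (float(finite.mean()), float(finite.std()))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_image, columns=["record", "metric", "value"])


METRICS_BY_TASK = {
    "regression": ("pearson", "ssim", "psnr"),
    "segmentation": ("f1",),
    "instance": ("ap50",),
}


def evaluate_pair(
    pred: np.ndarray, gt: np.ndarray, task: str, data_range: float | None = None
) -> dict[str, float]:
    """Task-appropriate metrics for one prediction/ground-truth pair."""
    pred = np.squeeze(np.asarray(pred))
    gt = np.squeeze(np.asarray(gt))
    if task == "regression":
        rng_val = (
            data_range
            if data_range is not None
            else float(max(gt.max() - gt.min(), 1e-8))
        )
        return {
            "pearson": pearson(pred, gt),
            "ssim": ssim(pred, gt, data_range=rng_val),
            "psnr": psnr(pred, gt, data_range=rng_val),
        }
    if task == "segmentation":
        return {"f1": f1_pixel(pred > 0.5 if pred.dtype.kind == "f" else pred, gt)}
    if task == "instance":
        return {"ap50": average_precision(pred, gt)}
    raise ValueError(f"unknown task {task!r}")
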