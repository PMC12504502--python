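"""Training losses and segmentation evaluation metrics.

Losses operate on autograd tensors (so they backpropagate); metrics operate
on plain binary numpy arrays. The composite objective is purely additive:

    L_rec   = L_fore + L_back + L_whole          (three L1 reconstruction terms)
    L_mask  = L_bce + L_dice
    L_total = L_rec + L_mask

with unit weights throughout.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "BatchLosses",
    "ConfusionCounts",
    "l1_loss",
    "bce_loss",
    "dice_loss",
    "total_loss",
    "confusion",
    "metrics",
    "evaluate_dataset",
    "error_overlay",
]

BCE_CLAMP = 1e-7
DICE_EPS = 1e-6


@dataclass
class BatchLosses:
    """Named scalar losses for one batch (floats, detached from the graph)."""

    Lf: float = 0.0
    Lb: float = 0.0
    Ls: float = 0.0
    Lrec: float = 0.0
    Lbce: float = 0.0
    Ldice: float = 0.0
    Lmask: float = 0.0
    Ltotal: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check_shapes(a, b):
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if tuple(sa) != tuple(sb):
        raise ValueError(f"shape mismatch: {tuple(sa)} vs {tuple(sb)}")


def l1_loss(pred, target, reduction: str = "mean") -> Tensor:
    """Mean (default) or summed absolute deviation between two arrays."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    diff = (pred - target).abs()
    if reduction == "mean":
        return diff.mean()
    if reduction == "sum":
        return diff.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def bce_loss(prob, target) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1-1e-7]."""
    prob, target = as_tensor(prob), as_tensor(target)
    _check_shapes(prob, target)
    p = prob.clip(BCE_CLAMP, 1.0 - BCE_CLAMP)
    y = target
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def dice_loss(prob, target) -> Tensor:
    """Soft Dice loss: 1 - (2*sum(p*y)+eps)/(sum(p)+sum(y)+eps)."""
    prob, target = as_tensor(prob), as_tensor(target)
    _check_shapes(prob, target)
    inter = (prob * target).sum()
    denom = prob.sum() + target.sum()
    return 1.0 - (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)


def total_loss(
    lf: Tensor | None,
    lb: Tensor | None,
    ls: Tensor | None,
    lbce: Tensor,
    ldice: Tensor,
    reconstruction_enabled: bool = True,
) -> tuple[Tensor, BatchLosses]:
    """Combine components additively; returns (graph scalar, logged floats).

    When the reconstruction branch is ablated the three reconstruction terms
    are exactly zero and the total equals the mask loss.
    """
    lmask = lbce + ldice
    if reconstruction_enabled:
        if lf is None or lb is None or ls is None:
            raise ValueError("reconstruction losses required when the branch is enabled")
        lrec = lf + lb + ls
        ltotal = lrec + lmask
        log = BatchLosses(
            Lf=lf.item(), Lb=lb.item(), Ls=ls.item(), Lrec=lrec.item(),
            Lbce=lbce.item(), Ldice=ldice.item(),
            Lmask=lmask.item(), Ltotal=ltotal.item(),
        )
    else:
        ltotal = lmask
        log = BatchLosses(
            Lbce=lbce.item(), Ldice=ldice.item(),
            Lmask=lmask.item(), Ltotal=ltotal.item(),
        )
    return ltotal, log


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _as_binary(arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"expected binary array, found values {vals[:8]}")
    return arr


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted vs ground-truth mask."""
    pred = _as_binary(pred_mask)
    gt = _as_binary(gt_mask)
    _check_shapes(pred, gt)
    tp = int(np.sum((pred == 1) & (gt == 1)))
    fp = int(np.sum((pred == 1) & (gt == 0)))
    tn = int(np.sum((pred == 0) & (gt == 0)))
    fn = int(np.sum((pred == 0) & (gt == 1)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F1 and IoU from pixel counts.

    Degenerate cases: if both masks are empty (TP=FP=FN=0) all four metrics
    are 1; if TP=0 but a prediction or ground truth exists, all four are 0.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp == 0:
        val = 1.0 if fp == 0 and fn == 0 else 0.0
        return {"precision": val, "recall": val, "f1": val, "iou": val}
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2.0 * precision * recall / (precision + recall)
    iou = tp / (tp + fp + fn)
    return {"precision": precision, "recall": recall, "f1": f1, "iou": iou}


def evaluate_dataset(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    ids: list[str] | None = None,
) -> dict:
    """Per-image metrics, their arithmetic mean, and the global-pooled variant.

    The primary summary averages each metric over images (the convention of
    dermoscopy benchmarks); a single confusion over all pixels pooled is
    reported alongside for transparency.
    """
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (pred, gt) pair")
    if ids is None:
        ids = [f"sample_{i:04d}" for i in range(len(pairs))]
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for sid, (pred, gt) in zip(ids, pairs):
        c = confusion(pred, gt)
        m = metrics(c)
        m["id"] = sid
        per_image.append(m)
        pooled = ConfusionCounts(
            pooled.TP + c.TP, pooled.FP + c.FP, pooled.TN + c.TN, pooled.FN + c.FN
        )
    keys = ("precision", "recall", "f1", "iou")
    summary = {k: float(np.mean([m[k] for m in per_image])) for k in keys}
    return {
        "per_image": per_image,
        "mean": summary,
        "global_pooled": metrics(pooled),
        "n_images": len(pairs),
    }


def write_evaluation(result: dict, out_dir) -> None:
    """Emit per-image CSV and JSON summary of an evaluate_dataset result."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "precision", "recall", "f1", "iou"])
        for m in result["per_image"]:
            w.writerow([m["id"], m["precision"], m["recall"], m["f1"], m["iou"]])
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({k: result[k] for k in ("mean", "global_pooled", "n_images")}, fh, indent=2)


def error_overlay(pred_mask, gt_mask, image) -> np.ndarray:
    """Tint missed lesion pixels (FN) green and false alarms (FP) red.

    Returns a [3,H,W] RGB image; pixels where prediction and ground truth
    agree keep their original color.
    """
    pred = _as_binary(pred_mask)
    gt = _as_binary(gt_mask)
    if pred.ndim == 3:
        pred = pred[0]
    if gt.ndim == 3:
        gt = gt[0]
    image = np.asarray(image, dtype=np.float64)
    out = image.copy()
    fn = (pred == 0) & (gt == 1)
    fp = (pred == 1) & (gt == 0)
    blend = 0.6
    # green tint on FN
    out[1][fn] = (1 - blend) * image[1][fn] + blend * 1.0
    out[0][fn] *= 1 - blend
    out[2][fn] *= 1 - blend
    # red tint on FP
    out[0][fp] = (1 - blend) * image[0][fp] + blend * 1.0
    out[1][fp] *= 1 - blend
    out[2][fp] *= 1 - blend
    return np.clip(out, 0.0, 1.0)
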