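"""Segmentation metrics: per-object pixel accuracy and the pixel-weighted
mean success rate, plus a scene-level scoring harness.

Per-object accuracy
    P = K1 / K2 * 100 %
with K1 the pixel count credited to the object by the segmenter and K2 the
object's reference pixel count.  The scene-level mean success rate is
pixel-weighted across the m objects:
    sigma = sum_i z_i / sum_i Z_i * 100 %
(the ratio of summed counts, not the mean of per-object ratios), so large
objects weigh more and sigma reduces to P when m = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SegmentationScore",
    "pixel_accuracy",
    "mean_success_rate",
    "score_scene",
]


@dataclass
class SegmentationScore:
    per_object_accuracy: list[float]       # P_i, percent
    mean_success_rate: float               # sigma, percent
    matched_counts: list[int]              # z_i (= K1 per object)
    reference_counts: list[int]            # Z_i (= K2 per object)
    iou: list[float] = field(default_factory=list)
    assignment: list[int] = field(default_factory=list)  # truth -> pred index, -1 = unmatched


def pixel_accuracy(k1: int, k2: int) -> float:
    """Per-object accuracy P = 100 * K1 / K2 (percent)."""
    if k2 <= 0:
        raise ValueError("reference pixel count K2 must be > 0")
    if k1 < 0:
        raise ValueError("matched pixel count K1 must be >= 0")
    p = 100.0 * k1 / k2
    if p > 100.0:
        warnings.warn(f"accuracy {p:.1f}% exceeds 100%: over-segmentation "
                      "(K1 counts more pixels than the reference)")
    return p


def mean_success_rate(z, Z) -> float:
    """Pixel-weighted mean success rate sigma = 100 * sum(z) / sum(Z)."""
    z = np.asarray(z, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if z.shape != Z.shape or z.ndim != 1 or len(z) < 1:
        raise ValueError("z and Z must be equal-length 1-D sequences")
    tot = Z.sum()
    if tot <= 0:
        raise ValueError("sum of reference counts must be > 0")
    return 100.0 * float(z.sum()) / float(tot)


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def score_scene(
    predicted_masks: list[np.ndarray],
    truth_masks: list[np.ndarray],
    intersection_mode: bool = True,
) -> SegmentationScore:
    """Match predictions to truth by IoU (Hungarian) and apply the metrics.

    In intersection mode (default) K1 = |predicted & truth| per matched
    pair, so over-segmentation cannot inflate the score; with
    intersection_mode=False, K1 is the raw predicted-mask pixel count, as
    used when no reference masks exist.  Unmatched truth objects contribute
    z_i = 0.
    """
    if len(truth_masks) < 1:
        raise ValueError("need at least one truth mask")
    preds = [np.asarray(m, dtype=bool) for m in predicted_masks]
    truths = [np.asarray(m, dtype=bool) for m in truth_masks]
    nt, npred = len(truths), len(preds)
    iou_mat = np.zeros((nt, npred))
    for i, tm in enumerate(truths):
        for j, pm in enumerate(preds):
            iou_mat[i, j] = _iou(tm, pm)
    assignment = [-1] * nt
    if npred:
        rows, cols = linear_sum_assignment(-iou_mat)
        for r, c in zip(rows, cols):
            if iou_mat[r, c] > 0:
                assignment[r] = int(c)
    z, Z, per_p, ious = [], [], [], []
    for i, tm in enumerate(truths):
        k2 = int(tm.sum())
        j = assignment[i]
        if j >= 0:
            k1 = int(np.logical_and(preds[j], tm).sum()) if intersection_mode \
                else int(preds[j].sum())
            ious.append(iou_mat[i, j])
        else:
            k1 = 0
            ious.append(0.0)
        z.append(k1)
        Z.append(k2)
        per_p.append(pixel_accuracy(k1, k2) if k2 > 0 else 0.0)
    return SegmentationScore(
        per_object_accuracy=per_p,
        mean_success_rate=mean_success_rate(z, Z),
        matched_counts=z,
        reference_counts=Z,
        iou=ious,
        assignment=assignment,
    )
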