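"""Detection evaluation: confusion accounting, P/R/F1, AP, mAP, FPS.

A detection counts as a true positive when its IoU with a not-yet-
claimed ground-truth box reaches the threshold (0.5 by default, boundary
inclusive); each ground truth can be claimed once, so duplicates are
false positives.  AP uses 11-point interpolation by default (the
convention of VOC2007-era detectors); an all-point variant is available
since the two differ by a point or two of mAP.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_matrix

__all__ = ["ConfusionCounts", "EvalResult", "match_detections",
           "precision_recall_f1", "f1_score", "average_precision",
           "mean_average_precision", "evaluate_detections", "measure_fps"]


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap_per_query: list[float] = field(default_factory=list)
    map: float = 0.0
    fps: float | None = None


def match_detections(det_boxes: np.ndarray, det_scores: np.ndarray,
                     gt_boxes: np.ndarray, iou_threshold: float = 0.5,
                     ) -> tuple[ConfusionCounts, np.ndarray]:
    """Greedy score-ordered matching of detections to ground truths.

    Returns the confusion counts and a per-detection TP flag array in
    the original detection order.  Each ground truth is claimable once;
    a detection whose best *free* ground truth reaches the IoU threshold
    is a TP, anything else an FP; leftover ground truths are FNs.
    """
    det_boxes = np.asarray(det_boxes, dtype=float).reshape(-1, 4)
    det_scores = np.asarray(det_scores, dtype=float).ravel()
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    n_det, n_gt = len(det_boxes), len(gt_boxes)
    tp_flags = np.zeros(n_det, dtype=bool)
    if n_det and n_gt:
        overlaps = iou_matrix(det_boxes, gt_boxes)
        free = np.ones(n_gt, dtype=bool)
        for idx in np.argsort(-det_scores, kind="stable"):
            avail = np.flatnonzero(free)
            if len(avail) == 0:
                break
            best = avail[np.argmax(overlaps[idx, avail])]
            if overlaps[idx, best] >= iou_threshold:
                tp_flags[idx] = True
                free[best] = False
    tp = int(tp_flags.sum())
    counts = ConfusionCounts(tp=tp, fp=n_det - tp, fn=n_gt - tp)
    return counts, tp_flags


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        warnings.warn("no ground truth and no detections: metrics set to 0",
                      stacklevel=2)
        return 0.0, 0.0, 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    return precision, recall, f1_score(precision, recall)


def average_precision(tp_flags: np.ndarray, n_gt: int,
                      method: str = "11point") -> float:
    """AP of a ranked TP/FP flag list (descending score order).

    '11point': mean over recall levels {0, 0.1, ..., 1.0} of the max
    precision at recall >= r.  'all_point': area under the interpolated
    precision-recall curve.
    """
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truths")
    flags = np.asarray(tp_flags, dtype=bool).ravel()
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    precision = tp_cum / np.arange(1, len(flags) + 1)
    recall = tp_cum / n_gt
    if method == "11point":
        total = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r - 1e-12
            total += precision[mask].max() if mask.any() else 0.0
        return total / 11.0
    if method == "all_point":
        # precision envelope, then sum of recall-step areas
        prec_env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = 0.0
        area = 0.0
        for p, r in zip(prec_env, recall):
            if r > r_prev:
                area += (r - r_prev) * p
                r_prev = r
        return area
    raise ValueError(f"unknown AP method {method!r}")


def mean_average_precision(aps) -> float:
    """Arithmetic mean of per-query average precisions."""
    aps = list(aps)
    if not aps:
        raise ValueError("mean average precision needs at least one AP")
    return float(np.mean(aps))


def evaluate_detections(per_image_dets: list[dict],
                        per_image_gts: list[np.ndarray],
                        iou_threshold: float = 0.5,
                        ap_method: str = "11point") -> EvalResult:
    """Corpus-level evaluation over a list of images.

    ``per_image_dets`` entries carry normalized-or-pixel ``boxes`` and
    ``scores`` (same units as the ground truths); detections are pooled
    over the corpus for the ranked AP computation.
    """
    counts = ConfusionCounts()
    all_scores, all_flags = [], []
    n_gt_total = 0
    for dets, gts in zip(per_image_dets, per_image_gts):
        c, flags = match_detections(dets["boxes"], dets["scores"], gts,
                                    iou_threshold)
        counts = counts + c
        all_scores.append(np.asarray(dets["scores"], dtype=float).ravel())
        all_flags.append(flags)
        n_gt_total += len(np.asarray(gts).reshape(-1, 4))
    precision, recall, f1 = precision_recall_f1(counts)
    if n_gt_total > 0:
        scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
        flags = np.concatenate(all_flags) if all_flags else np.zeros(0, bool)
        order = np.argsort(-scores, kind="stable")
        ap = average_precision(flags[order], n_gt_total, ap_method)
        aps = [ap]
        map_ = mean_average_precision(aps)
    else:
        aps, map_ = [], 0.0
    return EvalResult(precision, recall, f1, aps, map_)


def measure_fps(detector, frames: np.ndarray, *, timer=time.perf_counter,
                ) -> float:
    """Frames per second of ``detector`` over a batch of frames.

    One warm-up call on the first frame is excluded from timing.
    Requires at least 10 frames for a stable estimate.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("cannot measure FPS on zero frames")
    if n < 10:
        raise ValueError(f"need at least 10 frames for FPS, got {n}")
    detector(frames[:1])  # warm-up
    t0 = timer()
    for i in range(n):
        detector(frames[i:i + 1])
    elapsed = timer() - t0
    return n / elapsed
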