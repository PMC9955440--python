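"""Default-box generation, IoU, matching, offset codec, and NMS.

Coordinate conventions
----------------------
Internal boxes are 0-based, half-open corner form ``(xmin, ymin, xmax,
ymax)`` in continuous pixel (or normalized [0,1]) units.  Default boxes
live in normalized center form ``(cx, cy, w, h)``.  The default-box
ordering is level-major, row-major within a level, ratio-minor — the
same canonical order the prediction heads flatten to, so index i of the
raw predictions always refers to default box i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "corner_to_center",
    "center_to_corner",
    "iou",
    "iou_matrix",
    "DefaultBoxSet",
    "generate_default_boxes",
    "MatchResult",
    "match_targets",
    "encode_boxes",
    "decode_boxes",
    "nms",
]

#: SSD offset variances (center, size)
DEFAULT_VARIANCES = (0.1, 0.2)


def corner_to_center(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    cx = (boxes[..., 0] + boxes[..., 2]) / 2
    cy = (boxes[..., 1] + boxes[..., 3]) / 2
    w = boxes[..., 2] - boxes[..., 0]
    h = boxes[..., 3] - boxes[..., 1]
    return np.stack([cx, cy, w, h], axis=-1)


def center_to_corner(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    half_w = boxes[..., 2] / 2
    half_h = boxes[..., 3] / 2
    return np.stack([boxes[..., 0] - half_w, boxes[..., 1] - half_h,
                     boxes[..., 0] + half_w, boxes[..., 1] + half_h], axis=-1)


def _check_boxes(b: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if b.shape[-1] != 4:
        raise ValueError("boxes must have 4 coordinates")
    if np.any(b[:, 2] <= b[:, 0]) or np.any(b[:, 3] <= b[:, 1]):
        raise ValueError("degenerate box: xmax must exceed xmin and ymax ymin")
    return b


def iou(a, b) -> float:
    """Intersection over union of two corner-form boxes."""
    return float(iou_matrix(_check_boxes(a), _check_boxes(b))[0, 0])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (N,4) x (M,4) -> (N,M).  Boxes are half-open corners."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union


@dataclass(frozen=True)
class DefaultBoxSet:
    """All default (prior) boxes of a pyramid, in canonical order.

    boxes_center: (N, 4) normalized (cx, cy, w, h)
    level_index:  (N,) pyramid level of each box
    scales:       per-level scale s_k
    aspect_ratios: the ratio sequence applied at every location
    """

    boxes_center: np.ndarray
    level_index: np.ndarray
    scales: tuple[float, ...]
    aspect_ratios: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.boxes_center)

    @property
    def boxes_corner(self) -> np.ndarray:
        return center_to_corner(self.boxes_center)


def level_scales(n_levels: int, s_min: float, s_max: float) -> np.ndarray:
    """Per-level scales, linear from s_min to s_max."""
    if not 0 < s_min < s_max <= 1:
        raise ValueError("require 0 < s_min < s_max <= 1")
    return np.linspace(s_min, s_max, n_levels)


def generate_default_boxes(pyramid, s_min: float = 0.2, s_max: float = 0.9,
                           ratios: tuple[float, ...] = (1.0, 1.0, 2.0),
                           ) -> DefaultBoxSet:
    """Generate the default-box set for a pyramid.

    Per location three boxes by default, matching the published aspect
    ratios between one and two: ratio 1 at scale s_k, ratio 1 at the
    geometric intermediate scale sqrt(s_k * s_{k+1}), and ratio 2 at
    s_k.  Centers sit at ((i+0.5)/H, (j+0.5)/W).

    ``pyramid`` needs only a ``levels`` attribute of (name, (H, W, C)).
    """
    if len(ratios) == 0:
        raise ValueError("ratios must be non-empty")
    levels = pyramid.levels
    scales = level_scales(len(levels), s_min, s_max)
    # s_{K+1} for the intermediate scale of the last level
    scales_ext = np.append(scales, 1.0)
    all_boxes = []
    level_idx = []
    for k, (_, shape) in enumerate(levels):
        h, w = shape[0], shape[1]
        s_k = scales[k]
        s_prime = np.sqrt(scales_ext[k] * scales_ext[k + 1])
        per_loc = []
        seen_ratio1 = False
        for r in ratios:
            if r == 1.0 and seen_ratio1:
                per_loc.append((s_prime, s_prime))  # second unit ratio
            else:
                per_loc.append((s_k * np.sqrt(r), s_k / np.sqrt(r)))
            seen_ratio1 = seen_ratio1 or r == 1.0
        cy, cx = np.meshgrid((np.arange(h) + 0.5) / h,
                             (np.arange(w) + 0.5) / w, indexing="ij")
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)  # (HW, 2)
        wh = np.array(per_loc)  # (B, 2) as (w, h)
        boxes = np.concatenate([
            np.repeat(centers, len(ratios), axis=0),
            np.tile(wh, (h * w, 1)),
        ], axis=1)
        all_boxes.append(boxes)
        level_idx.append(np.full(len(boxes), k, dtype=int))
    return DefaultBoxSet(
        boxes_center=np.concatenate(all_boxes, axis=0),
        level_index=np.concatenate(level_idx),
        scales=tuple(float(s) for s in scales),
        aspect_ratios=tuple(ratios),
    )


@dataclass
class MatchResult:
    """Per-default-box assignment produced by :func:`match_targets`.

    labels:   (N,) int — 0 background, 1 polyp (positive)
    gt_index: (N,) int — matched ground-truth index, -1 for background
    loc_targets: (N, 4) encoded regression offsets (zeros for background)
    """

    labels: np.ndarray
    gt_index: np.ndarray
    loc_targets: np.ndarray

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_positives(self) -> int:
        return int(self.positive_mask.sum())


def match_targets(gt: np.ndarray, defaults: DefaultBoxSet,
                  threshold: float = 0.5,
                  variances: tuple[float, float] = DEFAULT_VARIANCES,
                  ) -> MatchResult:
    """SSD bipartite-plus-threshold matching.

    Every ground-truth box is force-matched to its best-IoU default
    (ties broken by lowest default index); additionally any default with
    IoU >= threshold to some ground truth becomes positive and regresses
    toward its best ground truth.  Everything else is background.

    ``gt`` is an (M, 4) array of normalized corner boxes (M may be 0).
    """
    n = len(defaults)
    gt = np.asarray(gt, dtype=float).reshape(-1, 4)
    labels = np.zeros(n, dtype=int)
    gt_index = np.full(n, -1, dtype=int)
    loc_targets = np.zeros((n, 4), dtype=float)
    if len(gt) == 0:
        return MatchResult(labels, gt_index, loc_targets)
    overlap = iou_matrix(defaults.boxes_corner, gt)  # (N, M)
    best_gt = overlap.argmax(axis=1)
    best_gt_iou = overlap[np.arange(n), best_gt]
    pos = best_gt_iou >= threshold
    # force-match each GT to its best default (argmax -> lowest index tie)
    taken = set()
    for g in range(len(gt)):
        order = np.argsort(-overlap[:, g], kind="stable")
        for d in order:
            if d not in taken:
                taken.add(int(d))
                pos[d] = True
                best_gt[d] = g
                break
    labels[pos] = 1
    gt_index[pos] = best_gt[pos]
    loc_targets[pos] = encode_boxes(gt[best_gt[pos]],
                                    defaults.boxes_center[pos], variances)
    return MatchResult(labels, gt_index, loc_targets)


def encode_boxes(gt_corner: np.ndarray, default_center: np.ndarray,
                 variances: tuple[float, float] = DEFAULT_VARIANCES,
                 ) -> np.ndarray:
    """Corner-form ground truth -> variance-scaled offsets vs. defaults."""
    gt_corner = np.asarray(gt_corner, dtype=float)
    g = corner_to_center(gt_corner)
    d = np.asarray(default_center, dtype=float)
    if np.any(g[..., 2:] <= 0):
        raise ValueError("ground-truth box width/height must be positive")
    v1, v2 = variances
    return np.stack([
        (g[..., 0] - d[..., 0]) / d[..., 2] / v1,
        (g[..., 1] - d[..., 1]) / d[..., 3] / v1,
        np.log(g[..., 2] / d[..., 2]) / v2,
        np.log(g[..., 3] / d[..., 3]) / v2,
    ], axis=-1)


def decode_boxes(offsets: np.ndarray, default_center: np.ndarray,
                 variances: tuple[float, float] = DEFAULT_VARIANCES,
                 clip: bool = True) -> np.ndarray:
    """Exact inverse of :func:`encode_boxes`; corner form, clipped to [0,1]."""
    o = np.asarray(offsets, dtype=float)
    d = np.asarray(default_center, dtype=float)
    v1, v2 = variances
    cx = o[..., 0] * v1 * d[..., 2] + d[..., 0]
    cy = o[..., 1] * v1 * d[..., 3] + d[..., 1]
    w = np.exp(o[..., 2] * v2) * d[..., 2]
    h = np.exp(o[..., 3] * v2) * d[..., 3]
    corners = center_to_corner(np.stack([cx, cy, w, h], axis=-1))
    if clip:
        corners = corners.clip(0.0, 1.0)
    return corners


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.45,
        top_k: int = 200) -> np.ndarray:
    """Greedy non-maximum suppression.

    Returns indices into ``boxes`` of the survivors, sorted by
    descending score (ties broken by lower input index), pairwise IoU of
    survivors <= ``iou_threshold``, at most ``top_k`` kept.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).ravel()
    if len(boxes) == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    ious = iou_matrix(boxes, boxes)
    for idx in order:
        if len(keep) >= top_k:
            break
        if all(ious[idx, j] <= iou_threshold for j in keep):
            keep.append(int(idx))
    return np.array(keep, dtype=int)
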