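"""SSD multibox training objective.

Confidence term: softmax cross-entropy over the positives plus the
hardest mined negatives (at most ``neg_pos_ratio`` negatives per
positive, selected per image by confidence loss).  Localization term:
smooth-L1 between predicted offsets and encoded targets over positives
only.  Both terms are normalized by the number of positives in the
batch; total = confidence + alpha * localization.  A batch with no
positives contributes zero loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import MatchResult
from .pyramid import RawPredictions

__all__ = ["LossConfig", "LossBreakdown", "hard_negative_mine",
           "multibox_loss"]


@dataclass(frozen=True)
class LossConfig:
    """alpha weights the localization term; neg_pos_ratio caps mining."""

    alpha: float = 1.0
    neg_pos_ratio: float = 3.0


@dataclass
class LossBreakdown:
    confidence_loss: float
    localization_loss: float
    total: float
    n_positives: int


def hard_negative_mine(per_box_conf_loss: np.ndarray, positive_mask: np.ndarray,
                       ratio: float) -> np.ndarray:
    """Select the highest-loss background boxes.

    Keeps ``min(ratio * n_positives, n_available)`` negatives with the
    largest confidence loss; the returned mask is disjoint from
    ``positive_mask``.
    """
    per_box_conf_loss = np.asarray(per_box_conf_loss, dtype=float)
    positive_mask = np.asarray(positive_mask, dtype=bool)
    n_pos = int(positive_mask.sum())
    neg_mask = np.zeros_like(positive_mask)
    n_keep = min(int(ratio * n_pos), int((~positive_mask).sum()))
    if n_keep == 0:
        return neg_mask
    losses = np.where(positive_mask, -np.inf, per_box_conf_loss)
    order = np.argsort(-losses, kind="stable")
    neg_mask[order[:n_keep]] = True
    return neg_mask


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def _smooth_l1(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise smooth-L1 (transition at 1) and its derivative."""
    a = np.abs(x)
    val = np.where(a < 1.0, 0.5 * x * x, a - 0.5)
    grad = np.where(a < 1.0, x, np.sign(x))
    return val, grad


def multibox_loss(raw: RawPredictions, matches: list[MatchResult] | MatchResult,
                  cfg: LossConfig = LossConfig(), *, return_grads: bool = False):
    """Compute the SSD objective for a batch.

    ``matches`` holds one :class:`MatchResult` per image, aligned to the
    canonical default-box ordering of ``raw``.  With
    ``return_grads=True`` also returns ``(dloc, dconf)`` — gradients of
    the total loss w.r.t. the raw predictions.
    """
    if isinstance(matches, MatchResult):
        matches = [matches]
    n_img, n_boxes, n_classes = raw.conf.shape
    if len(matches) != n_img:
        raise ValueError("one MatchResult per image required")
    for m in matches:
        if len(m.labels) != n_boxes:
            raise ValueError(
                f"match result has {len(m.labels)} boxes but predictions "
                f"have {n_boxes}: ordering mismatch")

    labels = np.stack([m.labels for m in matches])            # (N, B)
    pos = labels > 0
    loc_t = np.stack([m.loc_targets for m in matches])        # (N, B, 4)
    n_pos_total = int(pos.sum())
    if n_pos_total == 0:
        zero = LossBreakdown(0.0, 0.0, 0.0, 0)
        if return_grads:
            return zero, np.zeros_like(raw.loc), np.zeros_like(raw.conf)
        return zero

    logp = _log_softmax(raw.conf.astype(np.float64))          # (N, B, C)
    per_box_ce = -np.take_along_axis(logp, labels[..., None], axis=-1)[..., 0]

    sel = np.zeros_like(pos)
    for i in range(n_img):
        neg = hard_negative_mine(per_box_ce[i], pos[i], cfg.neg_pos_ratio)
        sel[i] = pos[i] | neg
    conf_loss = float(per_box_ce[sel].sum() / n_pos_total)

    diff = raw.loc.astype(np.float64) - loc_t
    sl1, dsl1 = _smooth_l1(diff)
    loc_loss = float(sl1[pos].sum() / n_pos_total)

    total = conf_loss + cfg.alpha * loc_loss
    breakdown = LossBreakdown(conf_loss, loc_loss, total, n_pos_total)
    if not return_grads:
        return breakdown

    # d(conf)/d(logits): softmax - onehot on selected boxes
    probs = np.exp(logp)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    dconf = (probs - onehot) * sel[..., None] / n_pos_total
    dloc = np.where(pos[..., None], dsl1, 0.0) * (cfg.alpha / n_pos_total)
    return breakdown, dloc.astype(raw.loc.dtype), dconf.astype(raw.conf.dtype)
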