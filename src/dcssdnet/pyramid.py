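"""Multiscale feature pyramid (Dense_C1..Dense_C6) and prediction heads.

Levels 1-5 of the pyramid are the five post-transition backbone maps;
level 6 is an extra valid-padding convolution on the phase-6 dense-block
output that collapses it to a 1x1 map.  Each level carries two 3x3
spatial-preserving conv heads: one regressing B*4 box offsets and one
producing B*n_classes confidence logits per location.  Flattened
predictions follow the canonical default-box order (level-major,
row-major, ratio-minor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import ArchConfig, Backbone, FeatureMapShape, assemble_backbone
from .boxes import DefaultBoxSet, generate_default_boxes

__all__ = ["PyramidSpec", "RawPredictions", "attach_pyramid",
           "build_predictors", "DCSSDNet"]


@dataclass(frozen=True)
class PyramidSpec:
    """Six pyramid levels with per-location box count and class count."""

    levels: tuple[tuple[str, FeatureMapShape], ...]
    boxes_per_location: int = 3
    n_classes: int = 2  # background + polyp

    def __post_init__(self):
        if len(self.levels) != 6:
            raise ValueError(f"pyramid must have 6 levels, got {len(self.levels)}")
        sides = []
        for name, shape in self.levels:
            if shape.height != shape.width:
                raise ValueError(f"pyramid level {name} is not square: {shape}")
            sides.append(shape.height)
        if any(a <= b for a, b in zip(sides, sides[1:])):
            raise ValueError(f"pyramid sides must strictly decrease, got {sides}")

    @property
    def sides(self) -> tuple[int, ...]:
        return tuple(s.height for _, s in self.levels)

    @property
    def total_boxes(self) -> int:
        return sum(s.height * s.width * self.boxes_per_location
                   for _, s in self.levels)


@dataclass
class RawPredictions:
    """Flattened head outputs for one batch.

    loc:  (N, total_boxes, 4) offset regressions
    conf: (N, total_boxes, n_classes) raw logits
    """

    loc: np.ndarray
    conf: np.ndarray

    def __post_init__(self):
        if self.loc.shape[:2] != self.conf.shape[:2]:
            raise ValueError("localization and confidence box counts disagree")


def _level6_kernel(side: int) -> int:
    # a 3x3 valid conv needs side >= 3; smaller deep maps use a full-map kernel
    return min(3, side)


def attach_pyramid(backbone: Backbone, boxes_per_location: int = 3,
                   n_classes: int = 2, level6_filters: int = 256,
                   *, rng: np.random.Generator | None = None,
                   dtype=np.float32) -> tuple[PyramidSpec, nn.Conv2D]:
    """Derive the pyramid spec and the level-6 reduction conv.

    Returns ``(spec, level6_conv)``; the conv maps the phase-6 output
    (3x3x576 for the default config) to the 1x1 deepest level.
    """
    if rng is None:
        rng = np.random.default_rng(backbone.config.seed + 1)
    shape_by_name = dict(backbone.expected_shapes)
    tap_shapes = [shape_by_name[f"transition_{i}"] for i in range(1, 6)]
    d6 = shape_by_name["dense_6"]
    k6 = _level6_kernel(d6.height)
    side6 = nn.conv_out_side(d6.height, k6, 1, "valid")
    conv6 = nn.Conv2D(d6.channels, level6_filters, k6, padding="valid",
                      rng=rng, dtype=dtype, name="pyramid.level6")
    levels = tuple(
        [(f"Dense_C{i + 1}", s) for i, s in enumerate(tap_shapes)]
        + [("Dense_C6", FeatureMapShape(side6, side6, level6_filters))])
    return (PyramidSpec(levels, boxes_per_location, n_classes), conv6)


def build_predictors(pyramid: PyramidSpec, *,
                     rng: np.random.Generator | None = None,
                     dtype=np.float32) -> list[tuple[nn.Conv2D, nn.Conv2D]]:
    """Per-level (localization, confidence) 3x3 conv heads."""
    if rng is None:
        rng = np.random.default_rng(0)
    b, c = pyramid.boxes_per_location, pyramid.n_classes
    heads = []
    for name, shape in pyramid.levels:
        loc = nn.Conv2D(shape.channels, b * 4, 3, padding="same", rng=rng,
                        dtype=dtype, name=f"{name}.loc")
        conf = nn.Conv2D(shape.channels, b * c, 3, padding="same", rng=rng,
                         dtype=dtype, name=f"{name}.conf")
        heads.append((loc, conf))
    return heads


class DCSSDNet:
    """The full detector: DenseNet-46 backbone + pyramid + SSD heads.

    ``forward`` consumes a normalized image batch (N, S, S, 3) and
    returns :class:`RawPredictions`; ``backward`` accepts gradients of
    the flattened predictions and propagates them to every parameter.
    """

    def __init__(self, arch: ArchConfig | None = None,
                 boxes_per_location: int = 3, n_classes: int = 2,
                 s_min: float = 0.2, s_max: float = 0.9,
                 aspect_ratios: tuple[float, ...] = (1.0, 1.0, 2.0),
                 dtype=np.float32) -> None:
        self.arch = arch if arch is not None else ArchConfig()
        rng = np.random.default_rng(self.arch.seed)
        self.dtype = dtype
        self.backbone = assemble_backbone(self.arch, dtype=dtype, rng=rng)
        self.pyramid, self._level6_conv = attach_pyramid(
            self.backbone, boxes_per_location, n_classes, rng=rng, dtype=dtype)
        self.heads = build_predictors(self.pyramid, rng=rng, dtype=dtype)
        self.default_boxes: DefaultBoxSet = generate_default_boxes(
            self.pyramid, s_min, s_max, aspect_ratios)
        assert len(self.default_boxes) == self.pyramid.total_boxes
        self._cache = None

    # -- parameters --------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = self.backbone.params()
        out.extend(self._level6_conv.params())
        for loc, conf in self.heads:
            out.extend(loc.params())
            out.extend(conf.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"{i:04d}:{p.name}"] = p.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            key = f"{i:04d}:{p.name}"
            if p.value.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = state[key].astype(p.value.dtype)

    # -- forward / backward -------------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False) -> RawPredictions:
        s = self.arch.input_size
        if images.ndim != 4 or images.shape[1:3] != (s, s):
            raise ValueError(
                f"expected image batch shaped (N, {s}, {s}, "
                f"{self.arch.input_channels}), got {images.shape}")
        images = images.astype(self.dtype, copy=False)
        outputs = self.backbone.forward(images, train=train)
        taps = self.backbone.taps(outputs)
        feats = taps[:5] + [self._level6_conv.forward(taps[5], train=train)]
        n = images.shape[0]
        b, c = self.pyramid.boxes_per_location, self.pyramid.n_classes
        locs, confs, level_shapes = [], [], []
        for (loc_head, conf_head), feat in zip(self.heads, feats):
            lo = loc_head.forward(feat, train=train)
            co = conf_head.forward(feat, train=train)
            level_shapes.append(lo.shape)
            locs.append(lo.reshape(n, -1, 4))
            confs.append(co.reshape(n, -1, c))
        if train:
            self._cache = level_shapes
        return RawPredictions(loc=np.concatenate(locs, axis=1),
                              conf=np.concatenate(confs, axis=1))

    def backward(self, dloc: np.ndarray, dconf: np.ndarray) -> None:
        level_shapes, self._cache = self._cache, None
        n = dloc.shape[0]
        b, c = self.pyramid.boxes_per_location, self.pyramid.n_classes
        tap_grads: list[np.ndarray] = []
        offset = 0
        dfeat6 = None
        for i, ((loc_head, conf_head), shape) in enumerate(
                zip(self.heads, level_shapes)):
            _, h, w, _ = shape
            count = h * w * b
            dl = dloc[:, offset:offset + count, :].reshape(n, h, w, b * 4)
            dc = dconf[:, offset:offset + count, :].reshape(n, h, w, b * c)
            offset += count
            dfeat = loc_head.backward(np.ascontiguousarray(dl))
            dfeat = dfeat + conf_head.backward(np.ascontiguousarray(dc))
            if i < 5:
                tap_grads.append(dfeat)
            else:
                dfeat6 = self._level6_conv.backward(dfeat)
        tap_grads.append(dfeat6)
        self.backbone.backward(tap_grads)

    # -- inference ----------------------------------------------------------
    def predict(self, images: np.ndarray, score_threshold: float = 0.01,
                nms_iou: float = 0.45, top_k: int = 200,
                keep: int = 100) -> list[dict]:
        """Decode + NMS.  Returns one dict per image with normalized
        corner ``boxes``, ``scores`` and integer ``labels`` (1 = polyp)."""
        from .boxes import decode_boxes, nms as _nms

        raw = self.forward(images, train=False)
        z = raw.conf - raw.conf.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=-1, keepdims=True)
        results = []
        for i in range(images.shape[0]):
            decoded = decode_boxes(raw.loc[i], self.default_boxes.boxes_center)
            dets_boxes, dets_scores, dets_labels = [], [], []
            for cls in range(1, self.pyramid.n_classes):
                scores = probs[i, :, cls]
                sel = np.flatnonzero(scores >= score_threshold)
                if len(sel) == 0:
                    continue
                valid = sel[(decoded[sel, 2] > decoded[sel, 0])
                            & (decoded[sel, 3] > decoded[sel, 1])]
                if len(valid) == 0:
                    continue
                kept = _nms(decoded[valid], scores[valid], nms_iou, top_k)
                dets_boxes.append(decoded[valid][kept])
                dets_scores.append(scores[valid][kept])
                dets_labels.append(np.full(len(kept), cls, dtype=int))
            if dets_boxes:
                boxes_all = np.concatenate(dets_boxes)
                scores_all = np.concatenate(dets_scores)
                labels_all = np.concatenate(dets_labels)
                order = np.argsort(-scores_all, kind="stable")[:keep]
                results.append({"boxes": boxes_all[order],
                                "scores": scores_all[order],
                                "labels": labels_all[order]})
            else:
                results.append({"boxes": np.zeros((0, 4)),
                                "scores": np.zeros(0),
                                "labels": np.zeros(0, dtype=int)})
        return results
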