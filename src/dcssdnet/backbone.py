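"""Compact DenseNet-46 backbone.

The backbone is a stem block followed by six phases of dense blocks;
phases 1-5 each end in a transition block (1x1 conv + 2x2 pool with ceil
rounding), phase 6 does not.  Each dense-block base unit applies
ReLU -> 1x1 conv (4k filters) -> 3x3 conv (k filters) and concatenates
its k new channels onto its input, so after a phase with ``n`` base
blocks the channel count grows by ``n * k``.

Two surfaces are exposed: a pure shape-inference calculus
(:func:`infer_feature_shapes`) that performs the channel/spatial
arithmetic without allocating tensors, and real trainable components
built on :mod:`dcssdnet.nn` whose forward pass must agree with the
calculus checkpoint-for-checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from . import nn

__all__ = [
    "ArchConfig",
    "FeatureMapShape",
    "DenseBlockSpec",
    "infer_feature_shapes",
    "build_stem",
    "build_dense_block",
    "build_transition_block",
    "assemble_backbone",
    "Backbone",
]

#: input side below which the six-level pyramid degenerates (phase-5
#: transition output would drop under 2 pixels)
MIN_INPUT_SIZE = 129


class FeatureMapShape(NamedTuple):
    """(height, width, channels) of one feature map."""

    height: int
    width: int
    channels: int

    def validate(self) -> "FeatureMapShape":
        if min(self) < 1:
            raise ValueError(f"all shape components must be >= 1, got {self}")
        return self


@dataclass(frozen=True)
class ArchConfig:
    """Architecture knobs of the DenseNet-46 backbone.

    Defaults reproduce the published architecture: growth rate k=32,
    base-block counts [2,3,3,3,2,2], an Inception-style stem whose first
    convolution has 64 filters, no batch normalization, average-pool
    transitions, 299x299 RGB input.
    """

    growth_rate_k: int = 32
    base_block_counts: tuple[int, ...] = (2, 3, 3, 3, 2, 2)
    stem_enabled: bool = True
    stem_first_filters: int = 64
    stem_out_channels: int = 96
    batch_norm: bool = False
    transition_pool: str = "average"
    transition_compression: float = 1.0
    input_size: int = 299
    input_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.growth_rate_k < 1:
            raise ValueError("growth_rate_k must be a positive integer")
        if len(self.base_block_counts) != 6:
            raise ValueError(
                f"base_block_counts must have length 6, got "
                f"{len(self.base_block_counts)}")
        if any(n < 0 for n in self.base_block_counts):
            raise ValueError("base_block_counts must be nonnegative")
        if self.transition_pool not in ("average", "max"):
            raise ValueError(
                f"transition_pool must be 'average' or 'max', "
                f"got {self.transition_pool!r}")
        if self.input_size < MIN_INPUT_SIZE:
            raise ValueError(
                f"input_size {self.input_size} is too small: the six-level "
                f"pyramid needs at least {MIN_INPUT_SIZE} pixels")
        if not 0 < self.transition_compression <= 1:
            raise ValueError("transition_compression must be in (0, 1]")

    def with_(self, **kw) -> "ArchConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class DenseBlockSpec:
    """One dense block: n base units, each 4k 1x1 filters then k 3x3."""

    n_base_blocks: int
    output_filters_per_block: int
    bottleneck_filters: int = field(default=0)

    def __post_init__(self):
        if self.bottleneck_filters == 0:
            object.__setattr__(self, "bottleneck_filters",
                               4 * self.output_filters_per_block)
        if self.bottleneck_filters != 4 * self.output_filters_per_block:
            raise ValueError("bottleneck_filters must equal 4 x growth rate")


def _ceil_half(side: int) -> int:
    return -(-side // 2)


def infer_feature_shapes(config: ArchConfig) -> list[tuple[str, FeatureMapShape]]:
    """Pure shape arithmetic for the whole backbone.

    Returns the 12 checkpoints: stem output, then each phase's dense-block
    output and (phases 1-5) post-transition output.  No tensors are
    allocated; the dense-block rule is ``c_out = c_in + n * k`` and each
    transition halves both spatial sides with ceil rounding while keeping
    the channel count (times the compression factor, 1 by default).
    """
    side = _ceil_half(_ceil_half(config.input_size))  # two stride-2 stem stages
    shapes: list[tuple[str, FeatureMapShape]] = [
        ("stem", FeatureMapShape(side, side, config.stem_out_channels).validate())
    ]
    ch = config.stem_out_channels
    for phase, n_base in enumerate(config.base_block_counts, start=1):
        ch = ch + n_base * config.growth_rate_k
        shapes.append((f"dense_{phase}",
                       FeatureMapShape(side, side, ch).validate()))
        if phase < 6:
            side = _ceil_half(side)
            ch = int(round(ch * config.transition_compression))
            shapes.append((f"transition_{phase}",
                           FeatureMapShape(side, side, ch).validate()))
    if shapes[-2][1].height < 2:  # phase-5 transition output
        raise ValueError(
            f"input_size {config.input_size} cannot sustain six strictly "
            "decreasing pyramid levels")
    return shapes


# ---------------------------------------------------------------------------
# trainable components


class _ConcatUnit(nn.Layer):
    """One dense base unit: concat(x, conv2(conv1(relu(x)))).

    The identity branch carries the raw (pre-ReLU) input; the transform
    branch is ReLU -> [BN] -> 1x1 conv (4k) -> [BN] -> 3x3 conv (k).
    """

    def __init__(self, in_ch: int, k: int, batch_norm: bool, *,
                 rng: np.random.Generator, dtype, name: str) -> None:
        layers: list[nn.Layer] = [nn.ReLU()]
        if batch_norm:
            layers.append(nn.BatchNorm2D(in_ch, dtype=dtype, name=f"{name}.bn1"))
        layers.append(nn.Conv2D(in_ch, 4 * k, 1, rng=rng, dtype=dtype,
                                name=f"{name}.conv1x1"))
        if batch_norm:
            layers.append(nn.BatchNorm2D(4 * k, dtype=dtype, name=f"{name}.bn2"))
        layers.append(nn.Conv2D(4 * k, k, 3, padding="same", rng=rng,
                                dtype=dtype, name=f"{name}.conv3x3"))
        self.branch = nn.Sequential(*layers)
        self.in_ch = in_ch
        self.k = k

    def params(self):
        return self.branch.params()

    def forward(self, x, train=False):
        y = self.branch.forward(x, train=train)
        return np.concatenate([x, y], axis=3)

    def backward(self, dout):
        dx = dout[..., :self.in_ch]
        dy = dout[..., self.in_ch:]
        return dx + self.branch.backward(dy)


def build_stem(config: ArchConfig, *, rng: np.random.Generator | None = None,
               dtype=np.float32) -> nn.Sequential:
    """Stem block mapping (S, S, 3) to (ceil(S/4), ceil(S/4), 96).

    Inception-style: 3x3 stride-2 conv (``stem_first_filters``), a 3x3
    conv, an asymmetric 1x7 / 7x1 pair, then a 3x3 stride-2 conv to the
    stem output width; ReLU after every conv.  With ``stem_enabled``
    off, the conventional DenseNet entry is used instead (7x7 stride-2
    conv + 3x3 stride-2 max pool) with the same output contract.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    c_in, f, out = config.input_channels, config.stem_first_filters, config.stem_out_channels
    if not config.stem_enabled:
        return nn.Sequential(
            nn.Conv2D(c_in, out, 7, stride=2, padding="same", rng=rng,
                      dtype=dtype, name="entry.conv7x7"),
            nn.ReLU(),
            _MaxPool3x3Stride2(),
        )
    return nn.Sequential(
        nn.Conv2D(c_in, f, 3, stride=2, padding="same", rng=rng, dtype=dtype,
                  name="stem.conv1"),
        nn.ReLU(),
        nn.Conv2D(f, f, 3, padding="same", rng=rng, dtype=dtype,
                  name="stem.conv2"),
        nn.ReLU(),
        nn.Conv2D(f, f, (1, 7), padding="same", rng=rng, dtype=dtype,
                  name="stem.conv1x7"),
        nn.ReLU(),
        nn.Conv2D(f, f, (7, 1), padding="same", rng=rng, dtype=dtype,
                  name="stem.conv7x1"),
        nn.ReLU(),
        nn.Conv2D(f, out, 3, stride=2, padding="same", rng=rng, dtype=dtype,
                  name="stem.conv_out"),
        nn.ReLU(),
    )


class _MaxPool3x3Stride2(nn.Layer):
    """3x3 stride-2 max pool with SAME (ceil) semantics."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        pt, pb = nn.same_pad(h, 3, 2)
        pl, pr = nn.same_pad(w, 3, 2)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        ho, wo = -(-h // 2), -(-w // 2)
        s0, s1, s2, s3 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, shape=(n, ho, wo, 3, 3, c),
            strides=(s0, 2 * s1, 2 * s2, s1, s2, s3), writeable=False)
        out = win.max(axis=(3, 4))
        if train:
            self._cache = (xp.shape, (pt, pl), x.shape, win, out)
        return out

    def backward(self, dout):
        xp_shape, (pt, pl), in_shape, win, out = self._cache
        self._cache = None
        mask = win == out[:, :, :, None, None, :]
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        n, ho, wo = dout.shape[:3]
        d = mask * dout[:, :, :, None, None, :]
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + 2 * ho:2, j:j + 2 * wo:2, :] += d[:, :, :, i, j, :]
        h, w = in_shape[1], in_shape[2]
        return dxp[:, pt:pt + h, pl:pl + w, :]


def build_dense_block(spec: DenseBlockSpec, in_shape: FeatureMapShape, *,
                      batch_norm: bool = False,
                      rng: np.random.Generator | None = None,
                      dtype=np.float32, name: str = "dense") -> nn.Sequential:
    """Dense block: ``n_base_blocks`` concat units growing channels by k each."""
    in_shape.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    k = spec.output_filters_per_block
    units = []
    ch = in_shape.channels
    for i in range(spec.n_base_blocks):
        units.append(_ConcatUnit(ch, k, batch_norm, rng=rng, dtype=dtype,
                                 name=f"{name}.unit{i + 1}"))
        ch += k
    return nn.Sequential(*units)


def build_transition_block(in_shape: FeatureMapShape, pool: str = "average", *,
                           compression: float = 1.0,
                           rng: np.random.Generator | None = None,
                           dtype=np.float32,
                           name: str = "transition") -> nn.Sequential:
    """Transition: channel-preserving 1x1 conv + 2x2 ceil-mode pool."""
    in_shape.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    out_ch = int(round(in_shape.channels * compression))
    return nn.Sequential(
        nn.Conv2D(in_shape.channels, out_ch, 1, padding="valid", rng=rng,
                  dtype=dtype, name=f"{name}.conv1x1"),
        nn.Pool2x2(pool),
    )


class Backbone:
    """Assembled DenseNet-46 with six named tap points.

    Taps ``Dense_C1 .. Dense_C5`` are the five post-transition maps; tap
    ``Dense_C6`` is the phase-6 dense-block output (no transition).
    """

    TAP_NAMES = tuple(f"Dense_C{i}" for i in range(1, 7))

    def __init__(self, config: ArchConfig, *, dtype=np.float32,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.expected_shapes = infer_feature_shapes(config)
        shape_by_name = dict(self.expected_shapes)
        self.stages: list[tuple[str, nn.Layer]] = [
            ("stem", build_stem(config, rng=rng, dtype=dtype))]
        for phase, n_base in enumerate(config.base_block_counts, start=1):
            in_shape = (shape_by_name["stem"] if phase == 1
                        else shape_by_name[f"transition_{phase - 1}"])
            spec = DenseBlockSpec(n_base, config.growth_rate_k)
            self.stages.append((
                f"dense_{phase}",
                build_dense_block(spec, in_shape, batch_norm=config.batch_norm,
                                  rng=rng, dtype=dtype, name=f"dense{phase}")))
            if phase < 6:
                self.stages.append((
                    f"transition_{phase}",
                    build_transition_block(
                        shape_by_name[f"dense_{phase}"], config.transition_pool,
                        compression=config.transition_compression, rng=rng,
                        dtype=dtype, name=f"transition{phase}")))
        self._tap_stage_names = tuple(
            [f"transition_{i}" for i in range(1, 6)] + ["dense_6"])

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for _, stage in self.stages:
            out.extend(stage.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """Run the backbone; returns every stage output keyed by stage name."""
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1] != s or x.shape[2] != s:
            raise ValueError(
                f"expected input batch of shape (N, {s}, {s}, "
                f"{self.config.input_channels}), got {x.shape}")
        outputs: dict[str, np.ndarray] = {}
        for name, stage in self.stages:
            x = stage.forward(x, train=train)
            outputs[name] = x
        return outputs

    def taps(self, outputs: dict[str, np.ndarray]) -> list[np.ndarray]:
        return [outputs[n] for n in self._tap_stage_names]

    def backward(self, tap_grads: list[np.ndarray]) -> None:
        """Backpropagate gradients supplied at the six tap points."""
        grads = dict(zip(self._tap_stage_names, tap_grads))
        dout = None
        for name, stage in reversed(self.stages):
            if dout is None:
                dout = grads[name]
            elif name in grads:
                dout = dout + grads[name]
            dout = stage.backward(dout)


def assemble_backbone(config: ArchConfig, *, dtype=np.float32,
                      rng: np.random.Generator | None = None) -> Backbone:
    """Build the full backbone; see :class:`Backbone`."""
    return Backbone(config, dtype=dtype, rng=rng)
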