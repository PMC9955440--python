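"""Minimal numpy neural-network layer library.

Implements exactly the layer vocabulary the detector needs — 2-D
convolution (im2col + BLAS matmul), ReLU, batch normalization, 2x2
pooling with ceil rounding, and the Adam optimizer — each with a manual
backward pass.  Tensors use NHWC layout throughout; every layer caches
what its backward pass needs on ``forward`` and releases it afterwards.

Determinism: all randomness goes through an explicit
``numpy.random.Generator``; with fixed weights a forward pass is a pure
function of its input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "ReLU",
    "BatchNorm2D",
    "Pool2x2",
    "Sequential",
    "Adam",
    "same_pad",
    "conv_out_side",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: ``forward(x)`` then ``backward(dout)`` -> dx."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def conv_out_side(side: int, k: int, stride: int, padding: str) -> int:
    """Output side of a conv/pool along one spatial axis.

    ``padding='same'`` uses TF-style SAME semantics: out = ceil(side/stride),
    which is also the ceil-rounding rule the pooling stages rely on.
    """
    if padding == "same":
        return -(-side // stride)
    if padding == "valid":
        return (side - k) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


def same_pad(side: int, k: int, stride: int) -> tuple[int, int]:
    """(before, after) zero-padding for SAME semantics along one axis."""
    out = -(-side // stride)
    total = max((out - 1) * stride + k - side, 0)
    before = total // 2
    return before, total - before


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            pads: tuple[int, int, int, int]) -> tuple[np.ndarray, tuple]:
    """Return (cols, geometry).  cols is (N*Ho*Wo, kh*kw*C)."""
    pt, pb, pl, pr = pads
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    n, hp, wp, c = x.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, kh, kw, c),
        strides=(s0, s1 * sh, s2 * sw, s1, s2, s3),
        writeable=False,
    )
    cols = windows.reshape(n * ho * wo, kh * kw * c)  # copies
    return cols, (n, ho, wo, hp, wp, c)


def _col2im(dcols: np.ndarray, geom: tuple, kh: int, kw: int, sh: int, sw: int,
            pads: tuple[int, int, int, int], in_shape: tuple) -> np.ndarray:
    n, ho, wo, hp, wp, c = geom
    pt, pb, pl, pr = pads
    dx = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dx[:, i:i + ho * sh:sh, j:j + wo * sw:sw, :] += d6[:, :, :, i, j, :]
    h, w = in_shape[1], in_shape[2]
    return dx[:, pt:pt + h, pl:pl + w, :]


class Conv2D(Layer):
    """2-D convolution, NHWC, He fan-in initialized.

    padding: 'same' (spatial-preserving at stride 1, ceil-halving at
    stride 2) or 'valid'.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int | tuple[int, int],
                 stride: int = 1, padding: str = "same", *,
                 rng: np.random.Generator, dtype=np.float32,
                 name: str = "conv") -> None:
        kh, kw = (ksize, ksize) if isinstance(ksize, int) else ksize
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.padding = padding
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = kh * kw * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh * kw * in_ch, out_ch))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pads(self, h: int, w: int) -> tuple[int, int, int, int]:
        if self.padding == "valid":
            return (0, 0, 0, 0)
        pt, pb = same_pad(h, self.kh, self.stride)
        pl, pr = same_pad(w, self.kw, self.stride)
        return (pt, pb, pl, pr)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[3] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} input channels, got {x.shape[3]}")
        pads = self._pads(x.shape[1], x.shape[2])
        cols, geom = _im2col(x, self.kh, self.kw, self.stride, self.stride, pads)
        out = cols @ self.w.value + self.b.value
        n, ho, wo = geom[0], geom[1], geom[2]
        if train:
            self._cache = (cols, geom, pads, x.shape)
        return out.reshape(n, ho, wo, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, geom, pads, in_shape = self._cache
        self._cache = None
        dmat = dout.reshape(-1, self.out_ch)
        self.w.grad += cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.value.T
        return _col2im(dcols, geom, self.kh, self.kw, self.stride, self.stride,
                       pads, in_shape)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dout * mask


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        m = shape[0] * shape[1] * shape[2]
        axes = (0, 1, 2)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        return (inv / m) * (m * dxhat - dxhat.sum(axis=axes)
                            - xhat * (dxhat * xhat).sum(axis=axes))


class Pool2x2(Layer):
    """2x2 stride-2 pooling with ceil rounding (odd sides pad by one).

    mode 'average' excludes the padding from the divisor; mode 'max' pads
    with -inf.  This is the transition-block downsampler, so ceil rounding
    is load-bearing: it is what maps 75->38 and 5->3.
    """

    def __init__(self, mode: str = "average") -> None:
        if mode not in ("average", "max"):
            raise ValueError(f"pool mode must be 'average' or 'max', got {mode!r}")
        self.mode = mode
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        ph, pw = h % 2, w % 2
        if self.mode == "max":
            xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                        constant_values=-np.inf)
        else:
            xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
        ho, wo = (h + ph) // 2, (w + pw) // 2
        win = xp.reshape(n, ho, 2, wo, 2, c)
        if self.mode == "max":
            out = win.max(axis=(2, 4))
            if train:
                self._cache = ("max", win == out[:, :, None, :, None, :],
                               (n, h, w, c, ho, wo))
        else:
            counts = np.ones((h + ph, w + pw), dtype=x.dtype)
            if ph:
                counts[h:, :] = 0
            if pw:
                counts[:, w:] = 0
            cnt = counts.reshape(ho, 2, wo, 2).sum(axis=(1, 3))
            out = win.sum(axis=(2, 4)) / cnt[None, :, :, None]
            if train:
                self._cache = ("avg", cnt, (n, h, w, c, ho, wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kind, aux, (n, h, w, c, ho, wo) = self._cache
        self._cache = None
        if kind == "max":
            d = aux * dout[:, :, None, :, None, :]
        else:
            d = (dout / aux[None, :, :, None])[:, :, None, :, None, :]
            d = np.broadcast_to(d, (n, ho, 2, wo, 2, c))
        dx = d.reshape(n, 2 * ho, 2 * wo, c)
        return dx[:, :h, :w, :]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.epsilon = beta1, beta2, epsilon
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.epsilon)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
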