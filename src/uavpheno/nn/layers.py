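"""Layers: explicit forward/backward, NCHW layout.

Each layer caches what its backward pass needs from the most recent
forward call, so a layer instance belongs to exactly one network path.
Parameters accumulate gradients (``zero_grad`` between steps).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), He-initialized.

    ``pad=None`` keeps the spatial size at stride 1 ("same" padding for
    odd kernels); pass an integer for explicit padding.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, (cout, cin, k, k)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"Conv2d expects {self.cin} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = self.W.value.reshape(self.cout, -1).T
        y = cols @ wmat
        if self.b is not None:
            y += self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += (dyf.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.reshape(self.cout, -1)).reshape(
            n, ho, wo, c, k, k
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 requires even dimensions, got {(h, w)}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr).reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class PixelShuffle(Layer):
    """(N, C*r^2, H, W) -> (N, C, H*r, W*r) sub-pixel rearrangement."""

    def __init__(self, r: int = 2):
        self.r = r

    def forward(self, x):
        n, crr, h, w = x.shape
        r = self.r
        if crr % (r * r):
            raise ValueError(f"channel count {crr} not divisible by r^2={r * r}")
        c = crr // (r * r)
        self._in_shape = x.shape
        y = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y).reshape(n, c, h * r, w * r)

    def backward(self, dy):
        n, crr, h, w = self._in_shape
        r = self.r
        c = crr // (r * r)
        dyr = dy.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(dyr).reshape(n, crr, h, w)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


class GlobalMean(Layer):
    """Mean over channel and spatial axes -> one scalar per sample."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dy[:, None, None, None] / (c * h * w), self._shape
        ).astype(dy.dtype).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def set_training(self, flag: bool):
        for l in self.layers:
            l.training = flag
            if isinstance(l, Sequential):
                l.set_training(flag)


def collect_params(*modules: Layer) -> list[Param]:
    return [p for m in modules for p in m.params()]


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    if len(params) != len(state):
        raise ValueError("state length does not match parameter count")
    for p, v in zip(params, state):
        if p.value.shape != v.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {v.shape}")
        p.value[...] = v
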