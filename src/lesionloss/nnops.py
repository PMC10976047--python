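"""Minimal explicit-backprop neural-network layers for 3D volumes.

The package trains a small 3D U-net on CPU with numpy only.  Each layer
implements ``forward(x)`` (caching what backward needs) and ``backward(dy)``
(returning ``dx`` and accumulating parameter gradients).  Convolutions are
evaluated as 27 shifted GEMMs rather than one huge im2col buffer, which
keeps peak memory proportional to the activation size.

All activations and parameters are float32; gradients flow in float32 as
well.  Every source of randomness is a ``numpy.random.Generator`` passed in
explicitly, so identical seeds give bitwise-identical weights.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Tuple

import numpy as np

__all__ = ["Conv3d", "GroupNorm", "ReLU", "MaxPool3d", "Upsample3d", "Adam"]

F32 = np.float32


class Layer:
    """Base class: parameters live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv3d(Layer):
    """3D convolution with odd kernel (1 or 3), stride 1, 'same' padding."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.cin, self.cout, self.k = cin, cout, kernel
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.params["w"] = (rng.standard_normal((cout, cin) + (kernel,) * 3)
                            * std).astype(F32)
        if bias:
            self.params["b"] = np.zeros(cout, dtype=F32)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else x
        self._xp = xp
        s = d * h * w
        y = np.zeros((b, self.cout, s), dtype=F32)
        wt = self.params["w"]
        for i, j, k in product(range(self.k), repeat=3):
            xs = np.ascontiguousarray(
                xp[:, :, i:i + d, j:j + h, k:k + w]).reshape(b, c, s)
            y += np.matmul(wt[:, :, i, j, k], xs)
        if "b" in self.params:
            y += self.params["b"][None, :, None]
        return y.reshape(b, self.cout, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, d, h, w = dy.shape
        s = d * h * w
        xp = self._xp
        dyf = dy.reshape(b, self.cout, s)
        wt = self.params["w"]
        dw = np.zeros_like(wt)
        for i, j, k in product(range(self.k), repeat=3):
            xs = np.ascontiguousarray(
                xp[:, :, i:i + d, j:j + h, k:k + w]).reshape(b, self.cin, s)
            dw[:, :, i, j, k] = np.tensordot(dyf, xs, axes=([0, 2], [0, 2]))
        self.grads["w"] = self.grads.get("w", 0) + dw
        if "b" in self.params:
            self.grads["b"] = self.grads.get("b", 0) + dyf.sum(axis=(0, 2))
        # dx: full correlation of dy with the flipped kernel
        p = self.pad
        dyp = np.pad(dy, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else dy
        dx = np.zeros((b, self.cin, s), dtype=F32)
        kk = self.k - 1
        for i, j, k in product(range(self.k), repeat=3):
            ds = np.ascontiguousarray(
                dyp[:, :, i:i + d, j:j + h, k:k + w]).reshape(b, self.cout, s)
            dx += np.matmul(wt[:, :, kk - i, kk - j, kk - k].T, ds)
        self._xp = None
        return dx.reshape(b, self.cin, d, h, w)


class GroupNorm(Layer):
    """Group normalisation with a fixed number of channels per group."""

    def __init__(self, channels: int, group_channels: int = 8,
                 eps: float = 1e-5) -> None:
        super().__init__()
        if channels % group_channels != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by the group size "
                f"({group_channels})"
            )
        self.c = channels
        self.g = channels // group_channels
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        xg = x.reshape(b, self.g, c // self.g, d, h, w)
        mu = xg.mean(axis=(2, 3, 4, 5), keepdims=True)
        var = xg.var(axis=(2, 3, 4, 5), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xn = ((xg - mu) * inv).reshape(b, c, d, h, w).astype(F32)
        self._xn, self._inv = xn, inv.astype(F32)
        return xn * self.params["gamma"][None, :, None, None, None] \
            + self.params["beta"][None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, d, h, w = dy.shape
        xn = self._xn
        self.grads["gamma"] = self.grads.get("gamma", 0) + \
            (dy * xn).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] = self.grads.get("beta", 0) + dy.sum(axis=(0, 2, 3, 4))
        dxn = dy * self.params["gamma"][None, :, None, None, None]
        gshape = (b, self.g, c // self.g, d, h, w)
        dxn_g = dxn.reshape(gshape)
        xn_g = xn.reshape(gshape)
        m1 = dxn_g.mean(axis=(2, 3, 4, 5), keepdims=True)
        m2 = (dxn_g * xn_g).mean(axis=(2, 3, 4, 5), keepdims=True)
        dx = (dxn_g - m1 - xn_g * m2) * self._inv
        self._xn = None
        return dx.reshape(b, c, d, h, w).astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, F32(0.0))
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """Max pooling with cube size 2, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        blocks = (x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
                   .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                   .reshape(b, c, d // 2, h // 2, w // 2, 8))
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, d, h, w = self._in_shape
        dblocks = np.zeros(dy.shape + (8,), dtype=F32)
        np.put_along_axis(dblocks, self._arg[..., None], dy[..., None], axis=-1)
        dx = (dblocks.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
                     .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                     .reshape(b, c, d, h, w))
        self._arg = None
        return dx


class Upsample3d(Layer):
    """Parameter-free nearest-neighbour x2 upsampling; backward sums blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, d, h, w = x.shape
        y = np.broadcast_to(
            x[:, :, :, None, :, None, :, None],
            (b, c, d, 2, h, 2, w, 2),
        )
        return np.ascontiguousarray(y).reshape(b, c, 2 * d, 2 * h, 2 * w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, d2, h2, w2 = dy.shape
        return (dy.reshape(b, c, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
                  .sum(axis=(3, 5, 7)).astype(F32))


class Adam:
    """Adam optimiser over a list of (layer, param-name) slots."""

    def __init__(self, layers: List[Layer], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.slots = [(layer, name) for layer in layers for name in layer.params]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def zero_grad(self) -> None:
        for layer, _ in self.slots:
            layer.grads = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] -= (self.lr * mhat /
                                   (np.sqrt(vhat) + self.eps)).astype(F32)
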