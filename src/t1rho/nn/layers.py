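"""Neural-network layers with explicit forward/backward passes.

Image tensors are channels-last (N, H, W, C) internally — convolutions are a
single im2col GEMM each way and elementwise layers never transpose. Vector
batches are (N, F). ``DTYPE`` (float32 by default) is the compute precision;
tests that finite-difference the gradients switch it to float64.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "Sequential",
    "Conv2d3x3",
    "Conv1x1",
    "BatchNorm2d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool2",
    "UpNearest2",
    "Linear",
    "AffineHead",
    "Limiter",
]

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. BatchNorm running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Conv2d3x3(Layer):
    """Same-padded 3x3 convolution on (N, H, W, C) tensors via im2col GEMM.

    The kernel is stored as a (C*9, O) matrix whose rows are ordered
    (channel, ki, kj) to match the im2col column layout.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, first: bool = False):
        std = np.sqrt(2.0 / (9 * cin))  # He init for the ReLU chains
        # rows ordered (kernel position k = 3*ki + kj, channel)
        self.W = Param(rng.normal(0.0, std, (9 * cin, cout)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout = cin, cout
        self.first = first  # first layer of a network: skip the input gradient
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        # block-contiguous gather: one (H, W*C)-shaped copy per kernel offset
        N, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((N, H, W, 9, C), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                cols[:, :, :, 3 * i + j, :] = xp[:, i : i + H, j : j + W, :]
        return cols.reshape(N * H * W, 9 * C), (N, H, W, C)

    def forward(self, x, train=True):
        cols, (N, H, W, C) = self._im2col(x)
        if train:
            self._cols, self._dims = cols, (N, H, W, C)
        out = cols @ self.W.data + self.b.data
        return out.reshape(N, H, W, self.cout)

    def backward(self, dy):
        N, H, W, C = self._dims
        dyf = dy.reshape(N * H * W, self.cout)
        self.W.grad += self._cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        if self.first:
            return None
        dcols = (dyf @ self.W.data.T).reshape(N, H, W, 9, C)
        dxp = np.zeros((N, H + 2, W + 2, C), dtype=dy.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, 3 * i + j, :]
        return dxp[:, 1:-1, 1:-1, :]


class Conv1x1(Layer):
    """Pointwise channel-mixing convolution (regressor head)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, std: float | None = None):
        std = np.sqrt(2.0 / cin) if std is None else std
        self.W = Param(rng.normal(0.0, std, (cin, cout)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy):
        xf = self._x.reshape(-1, self.W.data.shape[0])
        dyf = dy.reshape(-1, self.W.data.shape[1])
        self.W.grad += xf.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        return dy @ self.W.data.T


class _BatchNorm(Layer):
    """Shared machinery; channels sit on the last axis in both 1-D and 2-D."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=True):
        ax = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, ax)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy):
        xhat, inv, ax = self._cache
        m = dy.size / dy.shape[-1]
        self.gamma.grad += (dy * xhat).sum(axis=ax)
        self.beta.grad += dy.sum(axis=ax)
        g = self.gamma.data * inv
        return g * (dy - dy.sum(axis=ax) / m - xhat * (dy * xhat).sum(axis=ax) / m)


class BatchNorm2d(_BatchNorm):
    """BatchNorm over (N, H, W) per channel, channels-last."""


class BatchNorm1d(_BatchNorm):
    """BatchNorm over the batch axis of (N, F) activations."""


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 on (N, H, W, C)."""

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4))
        if train:
            mask = xr == out[:, :, None, :, None, :]
            # split ties evenly so the adjoint stays exact
            self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
            self._shape_in = x.shape
        return out

    def backward(self, dy):
        N, H, W, C = self._shape_in
        return (self._mask * dy[:, :, None, :, None, :]).reshape(N, H, W, C)


class UpNearest2(Layer):
    """Nearest-neighbor 2x upsampling; adjoint is 2x2 block summation."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        N, H, W, C = dy.shape
        return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, std: float | None = None):
        std = np.sqrt(2.0 / fin) if std is None else std
        self.W = Param(rng.normal(0.0, std, (fout, fin)))
        self.b = Param(np.zeros(fout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data


class AffineHead(Layer):
    """Fixed (non-trainable) affine rescaling from unit-scale activations to ms."""

    def __init__(self, scale: float, shift: float):
        self.scale = float(scale)
        self.shift = float(shift)

    def forward(self, x, train=True):
        return self.scale * x + self.shift

    def backward(self, dy):
        return self.scale * dy


class Limiter(Layer):
    """Prediction-range limiter: ``clip(relu(x) + ymin, ymin, ymax)``.

    Gradient is 1 on the open pass-band 0 < x < ymax - ymin and 0 where the
    ReLU or the upper clamp is active, which is what keeps mispredicted voxels
    from dominating the gradient.
    """

    def __init__(self, ymin: float, ymax: float):
        if not 0 < ymin < ymax:
            raise ValueError("need 0 < ymin < ymax")
        self.ymin = float(ymin)
        self.ymax = float(ymax)

    def forward(self, x, train=True):
        if train:
            self._mask = (x > 0) & (x < self.ymax - self.ymin)
        return np.clip(np.maximum(x, 0.0) + self.ymin, self.ymin, self.ymax)

    def backward(self, dy):
        return dy * self._mask
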