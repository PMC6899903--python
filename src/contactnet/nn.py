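"""Minimal NumPy neural-network engine for per-example map-to-map models.

Implements exactly the layers the contact network needs — 2D convolution
with dilation and "same" zero padding, instance normalization, ReLU,
convolutional Maxout — each as an object with ``forward(x)`` /
``backward(dy)`` methods and explicit parameter objects.  Gradients are
accumulated into ``Param.grad`` so a training loop can sum per-example
gradients before one optimizer step (gradient accumulation).

All layers operate on a single example of shape (C, H, W); batching is the
training loop's job, which keeps variable-size inputs padding-free.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator, dtype) -> np.ndarray:
    """Glorot/Xavier initialization drawn from the uniform distribution."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Dilated 2D convolution with zero 'same' padding via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dilation: int = 1,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel
        self.dilation = dilation
        fan_in = in_channels * kernel * kernel
        fan_out = out_channels * kernel * kernel
        self.W = Param(xavier_uniform((out_channels, fan_in), fan_in, fan_out, rng, dtype), "W")
        self.b = Param(np.zeros(out_channels, dtype=dtype), "b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        p = self.dilation * (self.k // 2)
        padded = np.pad(x, ((0, 0), (p, p), (p, p)))
        cols = np.empty((c, self.k, self.k, h, w), dtype=x.dtype)
        d = self.dilation
        for ki in range(self.k):
            for kj in range(self.k):
                cols[:, ki, kj] = padded[:, ki * d : ki * d + h, kj * d : kj * d + w]
        return cols.reshape(c * self.k * self.k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = self._im2col(x)
        y = self.W.data @ cols + self.b.data[:, None]
        self._cache = (cols, (c, h, w))
        return y.reshape(self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (c, h, w) = self._cache
        dy_flat = dy.reshape(self.cout, h * w)
        self.W.grad += dy_flat @ cols.T
        self.b.grad += dy_flat.sum(axis=1)
        dcols = (self.W.data.T @ dy_flat).reshape(c, self.k, self.k, h, w)
        p = self.dilation * (self.k // 2)
        dpad = np.zeros((c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        d = self.dilation
        for ki in range(self.k):
            for kj in range(self.k):
                dpad[:, ki * d : ki * d + h, kj * d : kj * d + w] += dcols[:, ki, kj]
        return dpad[:, p : p + h, p : p + w] if p else dpad


class InstanceNorm(Layer):
    """Per-channel normalization over spatial positions, with affine params."""

    def __init__(self, channels: int, eps: float = 1e-5, *, dtype=np.float32) -> None:
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), "gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "beta")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        g = self.gamma.data[:, None, None] * inv
        m = dy.mean(axis=(1, 2), keepdims=True)
        mx = (dy * xhat).mean(axis=(1, 2), keepdims=True)
        return g * (dy - m - xhat * mx)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxoutConv(Layer):
    """Convolution producing ``pieces`` parallel maps, reduced by elementwise max."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        pieces: int,
        kernel: int = 1,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        self.pieces = pieces
        self.cout = out_channels
        self.conv = Conv2d(in_channels, out_channels * pieces, kernel, rng=rng, dtype=dtype)

    def params(self) -> list[Param]:
        return self.conv.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self.conv.forward(x)
        _, h, w = z.shape
        z = z.reshape(self.pieces, self.cout, h, w)
        self._argmax = z.argmax(axis=0)
        return np.take_along_axis(z, self._argmax[None], axis=0)[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        dz = np.zeros((self.pieces, c, h, w), dtype=dy.dtype)
        np.put_along_axis(dz, self._argmax[None], dy[None], axis=0)
        return self.conv.backward(dz.reshape(self.pieces * c, h, w))


class ResidualBlock(Layer):
    """conv-ReLU-conv with an identity skip connection and a final ReLU.

    Both 5x5 convolutions share the block's dilation rate.
    """

    def __init__(self, channels: int, kernel: int, dilation: int, *, rng: np.random.Generator, dtype=np.float32) -> None:
        self.dilation = dilation
        self.conv1 = Conv2d(channels, channels, kernel, dilation, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, kernel, dilation, rng=rng, dtype=dtype)
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu2.forward(self.conv2.forward(h) + x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dx_skip = d
        dh = self.conv2.backward(d)
        dx = self.conv1.backward(self.relu1.backward(dh))
        return dx + dx_skip


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a list of :class:`Param` objects."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
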