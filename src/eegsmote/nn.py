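"""Minimal NumPy layers for 1-D convolutional networks.

Forward/backward passes are written out by hand (im2col convolutions,
explicit batch-norm gradients) so the lightweight seizure classifier can
train on CPU with no deep-learning framework.  Only the layer types the
inverted-residual architecture needs are provided: grouped 1-D
convolution (depthwise as the groups == channels case), batch norm,
clipped linear activation (ReLU6), global average pooling and a linear
head, plus Adam.

Shape convention: activations are (batch, channels, length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv1d", "BatchNorm1d", "ReLU6", "GlobalAvgPool1d",
           "Linear", "Adam", "softmax", "cross_entropy_grad"]


@dataclass
class Param:
    data: np.ndarray
    grad: np.ndarray

    @classmethod
    def zeros_grad(cls, data: np.ndarray) -> "Param":
        return cls(data=data, grad=np.zeros_like(data))


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Grouped 1-D convolution, 'same' padding (kernel odd), no bias.

    weight shape: (out_channels, in_channels // groups, kernel).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, groups: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels // groups, kernel))
        self.weight = Param.zeros_grad(w)

    def out_length(self, length: int) -> int:
        pad = self.kernel // 2
        return (length + 2 * pad - self.kernel) // self.stride + 1

    @property
    def n_params(self) -> int:
        return self.weight.data.size

    def macs(self, length: int) -> int:
        return (self.kernel * (self.in_channels // self.groups)
                * self.out_channels * self.out_length(length))

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, L = x.shape
        g, k, s = self.groups, self.kernel, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        patches = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        # (n, g, c/g, Lout, k)
        pg = patches.reshape(n, g, c // g, patches.shape[2], k)
        wg = self.weight.data.reshape(g, self.out_channels // g, c // g, k)
        out = np.einsum("ngclk,gock->ngol", pg, wg, optimize=True)
        self._cache = (pg, x.shape)
        return out.reshape(n, self.out_channels, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        pg, x_shape = self._cache
        n, c, L = x_shape
        g, k, s = self.groups, self.kernel, self.stride
        pad = k // 2
        Lout = grad.shape[2]
        gg = grad.reshape(n, g, self.out_channels // g, Lout)
        wg = self.weight.data.reshape(g, self.out_channels // g, c // g, k)
        self.weight.grad += np.einsum("ngol,ngclk->gock", gg, pg,
                                      optimize=True).reshape(
            self.weight.data.shape)
        gpatch = np.einsum("ngol,gock->ngclk", gg, wg, optimize=True)
        gpatch = gpatch.reshape(n, c, Lout, k)
        gx_pad = np.zeros((n, c, L + 2 * pad))
        pos0 = s * np.arange(Lout)
        for kk in range(k):  # positions unique within each tap -> safe +=
            gx_pad[:, :, pos0 + kk] += gpatch[:, :, :, kk]
        return gx_pad[:, :, pad:pad + L] if pad else gx_pad


class BatchNorm1d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param.zeros_grad(np.ones(channels))
        self.beta = Param.zeros_grad(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    @property
    def n_params(self) -> int:
        return 2 * self.channels

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.data[None, :, None] * xhat \
            + self.beta.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.data[None, :, None]
        if not training:
            return g * inv[None, :, None]
        m = shape[0] * shape[2]
        return (inv[None, :, None] / m) * (
            m * g - g.sum(axis=(0, 2), keepdims=True)
            - xhat * (g * xhat).sum(axis=(0, 2), keepdims=True))


class ReLU6(Layer):
    """Clipped linear activation min(max(x, 0), 6)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool1d(Layer):
    """Average over the temporal axis: (n, c, L) -> (n, c, 1)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad / self._L, self._L, axis=2)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(out_features, in_features))
        self.weight = Param.zeros_grad(w)
        self.bias = Param.zeros_grad(np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features

    @property
    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size

    def macs(self) -> int:
        return self.in_features * self.out_features

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n
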