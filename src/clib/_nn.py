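"""Minimal neural-network primitives on numpy arrays.

Layers operate on float64 NCHW tensors (or NxD matrices for dense layers),
cache what their backward pass needs, and expose parameters/gradients as
plain attributes so the SGD optimizer can update them in place.  Everything
is deterministic given the rng passed at construction.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "SGD",
    "state_checksum",
]


class Layer:
    """Base layer: forward/backward plus named parameter and buffer arrays."""

    param_names: tuple[str, ...] = ()
    buffer_names: tuple[str, ...] = ()
    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).copy() for n in self.param_names + self.buffer_names}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for n in self.param_names + self.buffer_names:
            arr = getattr(self, n)
            arr[...] = state[n]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*k*k, Ho*Wo) patch matrix (x already padded)."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, b, c, hp, wp, k, stride, ho, wo):
    d = dcols.reshape(b, c, k, k, ho, wo)
    dx = np.zeros((b, c, hp, wp))
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    return dx


class Conv2d(Layer):
    param_names = ("weight", "bias")

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(rng)
        fan_in = c_in * kernel * kernel
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        self.bias = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train=True):
        self._x_shape = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._padded_shape = x.shape
        self._cols, ho, wo = _im2col(x, self.kernel, self.stride)
        self._out_hw = (ho, wo)
        w2 = self.weight.reshape(self.weight.shape[0], -1)
        out = w2 @ self._cols + self.bias[:, None]
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, grad):
        b, f, ho, wo = grad.shape
        g2 = grad.reshape(b, f, ho * wo)
        self.dweight = np.einsum("bfl,bcl->fc", g2, self._cols).reshape(self.weight.shape)
        self.dbias = g2.sum(axis=(0, 2))
        w2 = self.weight.reshape(f, -1)
        dcols = np.matmul(w2.T, g2)
        _, c, hp, wp = self._padded_shape
        dx = _col2im(dcols, b, c, hp, wp, self.kernel, self.stride, ho, wo)
        if self.pad:
            dx = dx[:, :, self.pad : hp - self.pad, self.pad : wp - self.pad]
        return dx


class BatchNorm2d(Layer):
    param_names = ("gamma", "beta")
    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._ivar[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / n - self._xhat * s2 / n) * self._ivar[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(B,C,H,W) -> (B,C) spatial mean."""

    def forward(self, x, train=True):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad[:, :, None, None], grad.shape + (h, w)).copy() / (h * w)


class Linear(Layer):
    param_names = ("weight", "bias")

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = np.random.default_rng(rng)
        self.weight = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.bias = np.zeros(d_out)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad):
        self.dweight = self._x.T @ grad
        self.dbias = grad.sum(axis=0)
        return grad @ self.weight.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                out[f"{i}.{name}"] = arr
        return out

    def load_state(self, state):
        for i, layer in enumerate(self.layers):
            sub = {n: state[f"{i}.{n}"] for n in layer.param_names + layer.buffer_names}
            layer.load_state(sub)

    def set_trainable(self, flag: bool):
        for layer in self.layers:
            layer.trainable = flag


class SGD:
    """Momentum SGD over the trainable parameters of the given modules."""

    def __init__(self, modules: list[Layer], momentum: float = 0.9):
        self.slots: list[tuple[Layer, str]] = []
        for m in modules:
            layers = m.layers if isinstance(m, Sequential) else [m]
            for layer in layers:
                for name in layer.param_names:
                    self.slots.append((layer, name))
        self.momentum = momentum
        self.velocity = [np.zeros_like(getattr(l, n)) for l, n in self.slots]

    def step(self, lr: float):
        for (layer, name), vel in zip(self.slots, self.velocity):
            if not layer.trainable:
                continue
            grad = getattr(layer, "d" + name)
            vel *= self.momentum
            vel -= lr * grad
            getattr(layer, name).__iadd__(vel)


def state_checksum(*modules: Layer) -> str:
    """SHA-256 over all parameter/buffer bytes; constant iff weights unchanged."""
    h = hashlib.sha256()
    for m in modules:
        for name in sorted(m.state()):
            h.update(np.ascontiguousarray(m.state()[name]).tobytes())
    return h.hexdigest()
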