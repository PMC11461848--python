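"""Minimal NumPy neural-network framework for small 3D convolutional models.

Implements exactly the layer set needed by the volumetric extractors:
3x3x3 same-padding convolutions, ReLU, 2x2x2 max pooling, batch
normalization, global max pooling, dense layers, residual units and a
softmax cross-entropy head, all with hand-written backward passes.
Everything is driven by explicit ``numpy.random.Generator`` objects so a
given seed reproduces training bit-for-bit on a fixed BLAS.

Data layout is ``(batch, channels, depth, height, width)``.
"""

from __future__ import annotations

import copy
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3D",
    "ReLU",
    "MaxPool3D",
    "BatchNorm3D",
    "GlobalMaxPool3D",
    "Flatten",
    "Dense",
    "ResidualUnit",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "SGD",
]


class Layer:
    """Base layer: stateless unless it declares parameters."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 27
        # He initialization, appropriate for ReLU stacks
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((c_out, c_in, 3, 3, 3)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        """(B,C,D,H,W) -> (B*D*H*W, C*27) for 3^3 kernels with pad 1."""
        b, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        # win: (B, C, D, H, W, 3, 3, 3) -> (B, D, H, W, C, 3, 3, 3)
        win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        return np.ascontiguousarray(win).reshape(b * d * h * w, c * 27)

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        cols = self._im2col(x)
        wmat = self.w.reshape(self.c_out, -1).T  # (C_in*27, C_out)
        y = cols @ wmat + self.b
        y = y.reshape(b, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)
        if train:
            self._cols = cols
            self._xshape = x.shape
        else:
            self._cols = None
        return np.ascontiguousarray(y)

    def backward(self, dy):
        b, _, d, h, w = self._xshape
        dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(-1, self.c_out)
        self.dw = (self._cols.T @ dy_mat).T.reshape(self.w.shape)
        self.db = dy_mat.sum(axis=0)
        self._cols = None
        # dX = correlation of dy with kernels flipped and channel-transposed
        w_flip = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols_dy = self._im2col(dy)
        dx = cols_dy @ np.ascontiguousarray(w_flip).reshape(self.c_in, -1).T
        return np.ascontiguousarray(
            dx.reshape(b, d, h, w, self.c_in).transpose(0, 4, 1, 2, 3))


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; odd trailing voxels are cropped."""

    def forward(self, x, train=False):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2]
        blocks = xc.reshape(b, c, d2, 2, h2, 2, w2, 2)
        blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d2, h2, w2, 8)
        y = blocks.max(axis=-1)
        if train:
            self._xshape = x.shape
            self._argmax = blocks.argmax(axis=-1)
        return y

    def backward(self, dy):
        b, c, d, h, w = self._xshape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dblocks = np.zeros((b, c, d2, h2, w2, 8), dtype=dy.dtype)
        np.put_along_axis(dblocks, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dblocks = dblocks.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7)
        dx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = dblocks.reshape(
            b, c, d2 * 2, h2 * 2, w2 * 2)
        return dx


class BatchNorm3D(Layer):
    """Per-channel batch normalization over (batch, spatial) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    @staticmethod
    def _bshape(x):
        return (1, x.shape[1]) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        shp = self._bshape(x)
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            inv_sd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shp)) * inv_sd.reshape(shp)
            self._xhat, self._inv_sd, self._axes = xhat, inv_sd, axes
        else:
            inv_sd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shp)) * inv_sd.reshape(shp)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, dy):
        shp = self._bshape(dy)
        axes = self._axes
        n = dy.size // dy.shape[1]
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(shp)
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shp)
              - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(shp) / n)
        return dx * self._inv_sd.reshape(shp)


class GlobalMaxPool3D(Layer):
    """Max over all spatial positions: (B,C,D,H,W) -> (B,C)."""

    def forward(self, x, train=False):
        b, c = x.shape[:2]
        flat = x.reshape(b, c, -1)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._xshape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        b, c = dy.shape
        dflat = np.zeros((b, c, int(np.prod(self._xshape[2:]))), dtype=dy.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dy[..., None], axis=-1)
        return dflat.reshape(self._xshape)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential(Layer):
    """Ordered container of named layers with activation capture."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.layers = layers

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)

    def named_layers(self) -> Iterator[tuple[str, Layer]]:
        yield from self.layers

    def forward(self, x, train=False, capture: set[str] | None = None,
                captured: dict[str, np.ndarray] | None = None):
        for name, layer in self.layers:
            if isinstance(layer, (Sequential, ResidualUnit)):
                x = layer.forward(x, train=train, capture=capture,
                                  captured=captured)
            else:
                x = layer.forward(x, train=train)
            if capture and name in capture and captured is not None:
                captured[name] = x
        return x

    def backward(self, dy):
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameter_layers(self) -> Iterator[tuple[str, Layer]]:
        for name, layer in self.layers:
            if isinstance(layer, (Sequential, ResidualUnit)):
                for sub, l in layer.parameter_layers():
                    yield f"{name}.{sub}", l
            elif layer.params():
                yield name, layer


class ResidualUnit(Layer):
    """y = body(x) + x; the body must preserve shape and channel count."""

    def __init__(self, body: Sequential):
        self.body = body

    def forward(self, x, train=False, capture=None, captured=None):
        return self.body.forward(x, train=train, capture=capture,
                                 captured=captured) + x

    def backward(self, dy):
        return self.body.backward(dy) + dy

    def parameter_layers(self):
        yield from self.body.parameter_layers()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self):
        self.t += 1
        for lname, layer in self.net.parameter_layers():
            params, grads = layer.params(), layer.grads()
            for pname, p in params.items():
                g = grads[pname].astype(np.float64)
                if self.weight_decay and pname in ("w",):
                    g = g + self.weight_decay * p
                key = f"{lname}/{pname}"
                m = self.m.setdefault(key, np.zeros(p.shape))
                v = self.v.setdefault(key, np.zeros(p.shape))
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mh = m / (1 - self.b1 ** self.t)
                vh = v / (1 - self.b2 ** self.t)
                p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


class SGD:
    def __init__(self, net: Sequential, lr: float = 1e-2, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr, self.momentum = lr, momentum
        self.weight_decay = weight_decay
        self.vel: dict[str, np.ndarray] = {}

    def step(self):
        for lname, layer in self.net.parameter_layers():
            params, grads = layer.params(), layer.grads()
            for pname, p in params.items():
                g = grads[pname]
                if self.weight_decay and pname in ("w",):
                    g = g + self.weight_decay * p
                key = f"{lname}/{pname}"
                v = self.vel.setdefault(key, np.zeros_like(p))
                v[:] = self.momentum * v - self.lr * g
                p += v


def snapshot_params(net: Sequential) -> dict[str, dict[str, np.ndarray]]:
    return {lname: {k: v.copy() for k, v in layer.params().items()}
            for lname, layer in net.parameter_layers()}


def restore_params(net: Sequential, snap: dict[str, dict[str, np.ndarray]]) -> None:
    for lname, layer in net.parameter_layers():
        for k, v in layer.params().items():
            v[...] = snap[lname][k]


def clone_network(net: Sequential) -> Sequential:
    return copy.deepcopy(net)
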