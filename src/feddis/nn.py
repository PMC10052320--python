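"""Minimal NumPy neural-network engine.

Dense, strided convolution, transposed convolution, batch normalization,
LeakyReLU/Sigmoid activations, a ``Sequential`` container and an Adam
optimizer — everything the convolutional VAE and the task CNN need, with
hand-written backward passes. All arithmetic is float64 and fully
deterministic: given the same parameters, inputs and RNG the forward and
backward passes are bit-reproducible, which the federated-learning
equivalence guarantees in :mod:`feddis.federation` rely on.

Parameters and buffers are exchanged as ``OrderedDict[str, np.ndarray]``
state dicts (the ``ModelParameters`` currency of the federation layer).
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# im2col / col2im (kernel-offset formulation; loops only over the kh*kw
# offsets, vectorized over batch, channels and spatial positions)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride,
                                  j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride,
               j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: ``params`` are trainable, ``buffers`` are running state."""

    def __init__(self):
        self.params: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.grads: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=0):
        super().__init__()
        rng = _rng(rng)
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params["weight"] = rng.uniform(-limit, limit, (n_in, n_out))
        self.params["bias"] = np.zeros(n_out)
        self.zero_grad()

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dy):
        self.grads["weight"] += self._x.T @ dy
        self.grads["bias"] += dy.sum(axis=0)
        return dy @ self.params["weight"].T


class Conv2d(Layer):
    """Strided 2-D convolution, NCHW layout, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 pad: int = 1, rng=0):
        super().__init__()
        rng = _rng(rng)
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["weight"] = rng.uniform(
            -limit, limit, (c_out, c_in, kernel, kernel))
        self.params["bias"] = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.zero_grad()

    def forward(self, x, train=True):
        k = self.kernel
        cols, (oh, ow) = _im2col(x, k, k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        w = self.params["weight"].reshape(self.params["weight"].shape[0], -1)
        out = np.matmul(w, cols)  # (n, c_out, oh*ow)
        out += self.params["bias"][None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dy):
        n, c_out = dy.shape[:2]
        dyf = dy.reshape(n, c_out, -1)
        w = self.params["weight"].reshape(c_out, -1)
        self.grads["weight"] += np.einsum(
            "nfl,ncl->fc", dyf, self._cols).reshape(self.params["weight"].shape)
        self.grads["bias"] += dyf.sum(axis=(0, 2))
        dcols = np.matmul(w.T, dyf)
        k = self.kernel
        return _col2im(dcols, self._x_shape, k, k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Transposed (fractionally-strided) convolution; upsamples by ``stride``.

    Output size is ``stride*(H-1) + kernel - 2*pad`` — with the default
    kernel 4 / stride 2 / pad 1 the spatial size exactly doubles, mirroring
    :class:`Conv2d`'s halving.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 pad: int = 1, rng=0):
        super().__init__()
        rng = _rng(rng)
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["weight"] = rng.uniform(
            -limit, limit, (c_in, c_out, kernel, kernel))
        self.params["bias"] = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.zero_grad()

    def _out_shape(self, x_shape):
        n, _, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        c_out = self.params["weight"].shape[1]
        return (n, c_out, s * (h - 1) + k - 2 * p, s * (w - 1) + k - 2 * p)

    def forward(self, x, train=True):
        n, c_in, h, w = x.shape
        self._xf = x.reshape(n, c_in, h * w)
        w2 = self.params["weight"].reshape(c_in, -1)  # (c_in, c_out*k*k)
        cols = np.einsum("cf,ncl->nfl", w2, self._xf)
        out_shape = self._out_shape(x.shape)
        k = self.kernel
        out = _col2im(cols, out_shape, k, k, self.stride, self.pad)
        out += self.params["bias"][None, :, None, None]
        self._x_shape = x.shape
        return out

    def backward(self, dy):
        k = self.kernel
        dcols, _ = _im2col(dy, k, k, self.stride, self.pad)
        c_in = self._x_shape[1]
        w2 = self.params["weight"].reshape(c_in, -1)
        self.grads["weight"] += np.einsum(
            "ncl,nfl->cf", self._xf, dcols).reshape(self.params["weight"].shape)
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        dxf = np.einsum("cf,nfl->ncl", w2, dcols)
        return dxf.reshape(self._x_shape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.buffers["running_mean"] = np.zeros(c)
        self.buffers["running_var"] = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self.zero_grad()

    def forward(self, x, train=True):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mean)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std, self._train = xhat, std, train
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dy):
        axes = (0, 2, 3)
        xhat, std = self._xhat, self._std
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        if not self._train:
            return dy * g / std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return dx / std[None, :, None, None]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, train=True):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    # -- state-dict plumbing -------------------------------------------------
    def named_params(self):
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                yield f"{i}.{k}", layer.params, layer.grads, k

    def state_dict(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{prefix}{i}.{k}"] = v.copy()
            for k, v in layer.buffers.items():
                out[f"{prefix}{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = state[f"{prefix}{i}.{k}"].copy()
            for k in layer.buffers:
                layer.buffers[k] = state[f"{prefix}{i}.{k}"].copy()


# ---------------------------------------------------------------------------
# optimizer and losses
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (b1=0.9, b2=0.999)."""

    def __init__(self, lr: float = 1e-4, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, named_params):
        """``named_params``: iterable of (name, params-dict, grads-dict, key)."""
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for name, params, grads, key in named_params:
            g = grads[key]
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[key] = params[key] - self.lr * (m / bias1) / (
                np.sqrt(v / bias2) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient wrt the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
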