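"""Minimal CPU neural-network engine used by the spectrogram CNN.

Implements exactly the layer inventory the decoder architecture needs —
valid 2-D convolution, batch normalization, ReLU, 2x2 max-pooling with
configurable stride, dropout, fully-connected layers — together with a
softmax cross-entropy loss and the Adam optimizer.  Everything is plain
``numpy`` in float32; forward and backward passes are written against
im2col matrices so the heavy lifting is BLAS matrix multiplication.

Weight initialization follows the standard uniform fan-in scheme
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` for both weights and biases.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]


def _fan_in_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
                    dtype=np.float32) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base layer: stateless unless it declares parameters/buffers."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list:
        """List of (param_array, grad_array) pairs updated by the optimizer."""
        return []

    def buffers(self) -> list:
        """Non-trained state (e.g. batch-norm running moments) to snapshot."""
        return []


class Conv2d(Layer):
    """Valid (unpadded) 2-D convolution with stride 1, via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        k = kernel_size
        fan_in = in_channels * k * k
        self.k = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = _fan_in_uniform(rng, (out_channels, fan_in), fan_in, dtype)
        self.bias = _fan_in_uniform(rng, (out_channels,), fan_in, dtype)
        self.gw = np.zeros_like(self.weight)
        self.gb = np.zeros_like(self.bias)
        self._cols = None
        self._xshape = None

    def forward(self, x, train):
        b, c, h, w = x.shape
        k = self.k
        if h < k or w < k:
            raise ValueError(
                f"input {h}x{w} too small for a {k}x{k} valid convolution")
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # b,c,ho,wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=self.weight.dtype)
        out = cols @ self.weight.T + self.bias
        self._cols = cols
        self._xshape = (b, c, h, w, ho, wo)
        return out.reshape(b, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad):
        b, c, h, w, ho, wo = self._xshape
        k = self.k
        g2 = grad.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.out_channels)
        g2 = np.ascontiguousarray(g2, dtype=self.weight.dtype)
        self.gw[...] = g2.T @ self._cols
        self.gb[...] = g2.sum(axis=0)
        dcols = (g2 @ self.weight).reshape(b, ho, wo, c, k, k)
        dx = np.zeros((b, c, h, w), dtype=self.weight.dtype)
        # col2im: accumulate each kernel tap back onto the input grid
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def parameters(self):
        return [(self.weight, self.gw), (self.bias, self.gb)]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        axes = (0, 2, 3)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.ggamma[...] = (grad * xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        gmean = grad.mean(axis=axes)
        gxhat_mean = (grad * xhat).sum(axis=axes) / n
        dx = (self.gamma * inv)[None, :, None, None] * (
            grad
            - gmean[None, :, None, None]
            - xhat * gxhat_mean[None, :, None, None]
        )
        return dx.astype(self.gamma.dtype)

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def buffers(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """k x k max pooling; stride 1 by default (as in the decoder table)."""

    def __init__(self, kernel_size: int = 2, stride: int = 1):
        self.k = kernel_size
        self.stride = stride

    def _taps(self, x, ho, wo):
        k, s = self.k, self.stride
        for i in range(k):
            for j in range(k):
                yield i, j, x[:, :, i:i + s * ho:s, j:j + s * wo:s]

    def forward(self, x, train):
        k, s = self.k, self.stride
        h, w = x.shape[2], x.shape[3]
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        out = None
        for _, _, tap in self._taps(x, ho, wo):
            out = tap.copy() if out is None else np.maximum(out, tap)
        # route gradient to the first tap attaining the max (argmax order)
        chosen = np.full(out.shape, -1, dtype=np.int8)
        for t, (_, _, tap) in enumerate(self._taps(x, ho, wo)):
            np.copyto(chosen, t, where=(chosen < 0) & (tap == out))
        self._cache = (x.shape, chosen)
        return out

    def backward(self, grad):
        xshape, chosen = self._cache
        k, s = self.k, self.stride
        ho, wo = chosen.shape[2], chosen.shape[3]
        dx = np.zeros(xshape, dtype=grad.dtype)
        for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += grad * (chosen == t)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.weight = _fan_in_uniform(rng, (out_features, in_features), in_features, dtype)
        self.bias = _fan_in_uniform(rng, (out_features,), in_features, dtype)
        self.gw = np.zeros_like(self.weight)
        self.gb = np.zeros_like(self.bias)

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad):
        self.gw[...] = grad.T @ self._x
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.weight

    def parameters(self):
        return [(self.weight, self.gw), (self.bias, self.gb)]


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(grad.dtype)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers
        self.dtype = next((p.dtype for lay in layers for p, _ in lay.parameters()),
                          np.dtype(np.float32))

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def state(self) -> list:
        """Snapshot of all parameters and buffers (deep copies)."""
        arrs = []
        for layer in self.layers:
            for p, _ in layer.parameters():
                arrs.append(p.copy())
            for b in layer.buffers():
                arrs.append(b.copy())
        return arrs

    def load_state(self, arrs: list) -> None:
        i = 0
        for layer in self.layers:
            for p, _ in layer.parameters():
                p[...] = arrs[i]
                i += 1
            for b in layer.buffers():
                b[...] = arrs[i]
                i += 1

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in self.state():
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
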