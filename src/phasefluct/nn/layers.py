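"""Minimal deterministic NumPy neural-network layers.

Every layer implements ``forward(x, train)`` and ``backward(grad)``;
``backward`` must be called after ``forward`` (activations are cached on the
layer) and accumulates parameter gradients into ``Param.grad``.  All
computation is float32 and single-threaded NumPy, so runs are bitwise
reproducible on CPU for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Residual",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running stats)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2D convolution (cross-correlation) via im2col + GEMM."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.weight = Param(_he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, xp.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xp_shape, (n, oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out))
        self.weight.grad += gflat.T @ cols
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=0)
        dcols = (gflat @ self.weight.value).reshape(n, oh, ow, self.c_in, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + (oh - 1) * s + 1:s, j:j + (ow - 1) * s + 1:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, invstd, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return (g * invstd[None, :, None, None]).astype(np.float32)
        m = shape[0] * shape[2] * shape[3]
        # standard batch-norm backward through batch statistics
        dxhat_sum = g.sum(axis=(0, 2, 3))
        dxhat_xhat_sum = (g * xhat).sum(axis=(0, 2, 3))
        dx = (g - (dxhat_sum[None, :, None, None]
                   + xhat * dxhat_xhat_sum[None, :, None, None]) / m)
        return (dx * invstd[None, :, None, None]).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """Max pooling with kernel ``k``, stride ``s`` and symmetric padding.

    Ties go to the first (row-major) maximal element, deterministically.
    """

    def __init__(self, k: int = 2, stride: int | None = None, pad: int = 0):
        self.k = k
        self.stride = k if stride is None else stride
        self.pad = pad

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        else:
            xp = x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, oh, ow, k * k)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, xp.shape, (n, c, h, w, oh, ow))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad):
        idx, xp_shape, (n, c, h, w, oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ki, kj = np.divmod(idx, k)
        oy = np.arange(oh)[None, None, :, None]
        ox = np.arange(ow)[None, None, None, :]
        rows = oy * s + ki
        cols = ox * s + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, rows, cols), grad)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """Global average pooling: (N, C, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (n_out, n_in), n_in))
        self.bias = Param(np.zeros(n_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return (grad @ self.weight.value).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state(self):
        return [s for l in self.layers for s in l.state()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Residual(Layer):
    """Residual unit: ReLU(main(x) + shortcut(x)); identity shortcut if None."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def state(self):
        s = self.main.state()
        if self.shortcut is not None:
            s += self.shortcut.state()
        return s

    def forward(self, x, train=True):
        y = self.main.forward(x, train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        z = y + sc
        self._mask = z > 0
        return np.where(self._mask, z, 0.0).astype(np.float32)

    def backward(self, grad):
        g = np.where(self._mask, grad, 0.0).astype(np.float32)
        gx = self.main.backward(g)
        if self.shortcut is None:
            return (gx + g).astype(np.float32)
        return (gx + self.shortcut.backward(g)).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch.

    Returns ``(loss, dlogits, probs)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-30).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs.astype(np.float32)
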