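"""Minimal numpy layer library with manual backprop.

Shared training core for the DCGAN (``gan_balance``) and the severity
classifier (``cnn_classifier``). Data layout is NCHW throughout; every layer
exposes ``forward(x, train)`` / ``backward(grad)`` plus flat ``params`` /
``grads`` lists consumed by :class:`Adam`. All weight initialisation draws
from a caller-supplied :class:`numpy.random.Generator`, so builds are
bit-reproducible under a fixed seed.

Convolutions use im2col + BLAS matmuls in both directions; the input
gradient of a strided convolution (and the forward pass of a transposed
convolution) is computed as a stride-1 correlation of the zero-dilated
counterpart with the 180-degree-rotated kernel, which keeps everything on
the gather/matmul fast path instead of scatter-adds.
"""

from __future__ import annotations

import numpy as np

#: working precision of the layer library (weights, activations, optimizer
#: state). Single precision doubles throughput of the conv im2col copies and
#: BLAS calls without measurable effect on the desk-scale models.
DTYPE = np.float32

__all__ = [
    "Layer",
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "MaxPool2D",
    "LeakyReLU",
    "Tanh",
    "Dropout",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


def _dilate(x: np.ndarray, stride: int, extra: int) -> np.ndarray:
    """Insert stride-1 zeros between entries; append `extra` zero rows/cols."""
    if stride == 1 and extra == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros(
        (n, c, (h - 1) * stride + 1 + extra, (w - 1) * stride + 1 + extra),
        dtype=x.dtype,
    )
    out[:, :, :: stride or 1, :: stride or 1][:, :, :h, :w] = x
    return out


def _corr1(x: np.ndarray, w_mat: np.ndarray, k: int, pad: int, c_out: int) -> np.ndarray:
    """Stride-1 correlation of x with a (C*k*k, c_out) kernel matrix."""
    n = x.shape[0]
    ho = x.shape[2] + 2 * pad - k + 1
    wo = x.shape[3] + 2 * pad - k + 1
    cols = _im2col(x, k, 1, pad)
    out = cols.reshape(n * ho * wo, -1) @ w_mat
    return out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Conv2D(Layer):
    """Cross-correlation conv, stride/pad configurable, NCHW, weight
    layout (c_out, c_in*k*k)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
    ):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        n, _, h, w = x.shape
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.stride, self.pad)
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        out = self._cols.reshape(n * ho * wo, -1) @ self.w.T + self.b
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, ho, wo = grad.shape
        _, _, h, w = self._x_shape
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            n * ho * wo, self.c_out
        )
        self.grads[0][...] = g2.T @ self._cols.reshape(n * ho * wo, -1)
        self.grads[1][...] = g2.sum(axis=0)
        # input grad = stride-1 correlation of the dilated grad with the
        # 180-rotated kernel (transposed in/out channels)
        k, s, p = self.k, self.stride, self.pad
        slack = (h + 2 * p - k) - (ho - 1) * s
        g_up = _dilate(grad, s, slack)
        w4 = self.w.reshape(self.c_out, self.c_in, k, k)
        w_rot = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        w_mat = np.ascontiguousarray(
            w_rot.transpose(1, 2, 3, 0).reshape(self.c_out * k * k, self.c_in)
        )
        dx_pad = _corr1(g_up, w_mat, k, k - 1, self.c_in)
        return dx_pad[:, :, p : p + h, p : p + w]


class ConvTranspose2D(Layer):
    """Transpose of Conv2D(c_out -> c_in, k, stride, pad); upsamples by
    `stride`. Weight layout (c_in, c_out*k*k)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 2,
        pad: int = 1,
    ):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_in, c_out * k * k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        s, k, p = self.stride, self.k, self.pad
        return (h - 1) * s - 2 * p + k, (w - 1) * s - 2 * p + k

    def forward(self, x, train=False):
        n, _, h, w = x.shape
        self._x = x
        k, s, p = self.k, self.stride, self.pad
        # y = stride-1 correlation of the zero-dilated input with the
        # 180-rotated kernel: gather + matmul, no scatter
        x_up = _dilate(x, s, 0)
        w4 = self.w.reshape(self.c_in, self.c_out, k, k)
        w_rot = w4[:, :, ::-1, ::-1]  # (c_in, c_out, k, k)
        w_mat = np.ascontiguousarray(
            w_rot.transpose(0, 2, 3, 1).reshape(self.c_in * k * k, self.c_out)
        )
        out = _corr1(x_up, w_mat, k, k - 1 - p, self.c_out)
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        n, _, h, w = self._x.shape
        k, s, p = self.k, self.stride, self.pad
        gcols = _im2col(grad, k, s, p)  # (N, H*W, c_out*k*k)
        x2 = np.ascontiguousarray(self._x.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_in
        )
        gc2 = gcols.reshape(n * h * w, -1)
        self.grads[0][...] = x2.T @ gc2
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        dx = gc2 @ self.w.T  # (N*H*W, c_in)
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
            self._n = x.shape[0] * x.shape[2] * x.shape[3]
            return self.gamma[None, :, None, None] * self._xhat + self.beta[
                None, :, None, None
            ]
        xhat = (x - self.run_mean[None, :, None, None]) / np.sqrt(
            self.run_var + self.eps
        )[None, :, None, None]
        self._xhat = None
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        if self._xhat is None:
            raise RuntimeError("backward requires a training-mode forward pass")
        self.grads[0][...] = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        n = self._n
        dxhat = grad * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dxhat_xhat = (dxhat * self._xhat).mean(axis=(0, 2, 3))[
            None, :, None, None
        ]
        return (
            dxhat - mean_dxhat - self._xhat * mean_dxhat_xhat
        ) / self._std[None, :, None, None]


class MaxPool2D(Layer):
    """2x2 max pooling with floor on odd sides."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        s = self.size
        n, c, h, w = x.shape
        h2, w2 = h // s, w // s
        self._x_shape = x.shape
        xt = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        out = xt.max(axis=(3, 5))
        mask = xt == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, s * s)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h2, w2, s, s).transpose(
            0, 1, 2, 4, 3, 5
        )
        return out

    def backward(self, grad):
        s = self.size
        n, c, h, w = self._x_shape
        h2, w2 = h // s, w // s
        out = np.zeros(self._x_shape, dtype=grad.dtype)
        expanded = self._mask * grad[:, :, :, None, :, None]
        out[:, :, : h2 * s, : w2 * s] = expanded.reshape(n, c, h2 * s, w2 * s)
        return out


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.alpha * grad, grad)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam over a flat param/grad list; beta1=0.5 is the GAN-friendly setting."""

    def __init__(
        self,
        params: list,
        grads: list,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean (weighted) CE over the batch; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    ll = -np.log(p[np.arange(n), labels] + eps)
    if sample_weights is None:
        sample_weights = np.ones(n)
    wsum = sample_weights.sum()
    loss = float((ll * sample_weights).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weights / wsum)[:, None]
    return loss, grad
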