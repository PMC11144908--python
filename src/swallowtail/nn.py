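"""Minimal CPU neural-network primitives.

The networks in this package are deliberately tiny (a modified LeNet and
a 3-layer convolutional center regressor), so the layers are implemented
directly in numpy with hand-written backward passes: valid 5x5
convolutions via im2col, 2x2 max pooling, dense layers, ReLU, softmax
cross-entropy, and Adam.  Gradients are verified against finite
differences in the test suite.

Conventions: activations are float64 arrays shaped (N, C, H, W);
convolutions are stride-1 "valid".
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv_forward", "conv_backward",
    "maxpool_forward", "maxpool_backward",
    "relu_forward", "relu_backward",
    "dense_forward", "dense_backward",
    "softmax", "softmax_xent",
    "Adam", "init_conv", "init_dense",
]


def init_conv(rng: np.random.Generator, n_out: int, n_in: int, k: int):
    """He-initialized (weight, bias) for a k x k convolution."""
    scale = np.sqrt(2.0 / (n_in * k * k))
    return rng.normal(0.0, scale, (n_out, n_in, k, k)), np.zeros(n_out)


def init_dense(rng: np.random.Generator, n_in: int, n_out: int):
    scale = np.sqrt(2.0 / n_in)
    return rng.normal(0.0, scale, (n_in, n_out)), np.zeros(n_out)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Stride-1 valid convolution (cross-correlation) via im2col."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    oh, ow = h - kh + 1, wd - kw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * kh * kw
    )
    out = cols @ w.reshape(f, -1).T + b
    out = out.transpose(0, 2, 1).reshape(n, f, oh, ow)
    return out, (x.shape, cols, w)


def conv_backward(dout: np.ndarray, cache):
    x_shape, cols, w = cache
    n, c, h, wd = x_shape
    f, _, kh, kw = w.shape
    oh, ow = h - kh + 1, wd - kw + 1
    dflat = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (n, P, f)
    dw = np.einsum("npf,npk->fk", dflat, cols).reshape(w.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = (dflat @ w.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dx, dw, db


def maxpool_forward(x: np.ndarray):
    """2x2 max pooling, stride 2 (input H, W must be even)."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, (x.shape, mask)


def maxpool_backward(dout: np.ndarray, cache):
    x_shape, mask = cache
    n, c, h, w = x_shape
    dxr = mask * dout[:, :, :, None, :, None]
    return dxr.reshape(x_shape)


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask):
    return dout * mask


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def dense_backward(dout: np.ndarray, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
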