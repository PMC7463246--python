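"""Minimal NumPy layer primitives used by the fusion models.

Only the operations the fusion heads train through need a backward pass;
the convolutional backbone is frozen, so gradients never have to flow
through 3x3 convolutions or max-pooling.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d_3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding stride-1 3x3 convolution via im2col. x:(N,C,H,W),
    w:(O,C,3,3)."""
    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    out = cols.reshape(n * h * wd, c * 9) @ w.reshape(o, c * 9).T.astype(x.dtype)
    out = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out) + b[None, :, None, None].astype(x.dtype)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pooling; odd trailing rows/cols are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    return v.max(axis=(3, 5))


def avgpool2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 average pooling; odd trailing rows/cols are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    return v.mean(axis=(3, 5))


def avgpool2_backward(dout: np.ndarray, in_shape: tuple) -> np.ndarray:
    """Spread each pooled gradient evenly over its 2x2 source window."""
    n, c, h, w = in_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(in_shape, dout.dtype)
    expanded = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    dx[:, :, : h2 * 2, : w2 * 2] = expanded
    return dx


def gap(x: np.ndarray) -> np.ndarray:
    """Global average pooling (N,C,H,W) -> (N,C)."""
    return x.mean(axis=(2, 3))


def gap_backward(dout: np.ndarray, in_shape: tuple) -> np.ndarray:
    n, c, h, w = in_shape
    return np.broadcast_to(
        dout[:, :, None, None] / (h * w), in_shape
    ).astype(dout.dtype).copy()


def conv1x1(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise channel-mixing convolution. x:(N,C,H,W), w:(K,C)."""
    out = np.tensordot(x, w, axes=([1], [1]))  # (N,H,W,K)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + b[None, :, None, None]


def conv1x1_backward(dout, x, w):
    """Returns (dx, dw, db) for the pointwise convolution."""
    dw = np.tensordot(dout, x, axes=([0, 2, 3], [0, 2, 3]))  # (K,C)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.tensordot(dout, w, axes=([1], [0]))  # (N,H,W,C)
    return np.ascontiguousarray(dx.transpose(0, 3, 1, 2)), dw, db


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      training: bool, momentum: float = 0.1,
                      eps: float = 1e-5):
    """Batch normalization over all axes except the channel axis.

    Works for (N,D) feature vectors (channel axis 1) and (N,C,H,W) maps.
    ``running_mean``/``running_var`` are updated in place during
    training.  Returns (out, cache) with cache = (xhat, inv_std, axes).
    """
    axes = tuple(i for i in range(x.ndim) if i != 1)
    shape = [1] * x.ndim
    shape[1] = x.shape[1]
    if training:
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    return out, (xhat, inv_std, axes)


def batchnorm_backward(dout, cache, gamma, need_dx: bool = True):
    """Returns (dx, dgamma, dbeta); dx is None when not requested."""
    xhat, inv_std, axes = cache
    shape = [1] * dout.ndim
    shape[1] = dout.shape[1]
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    if not need_dx:
        return None, dgamma, dbeta
    m = np.prod([dout.shape[i] for i in axes])
    dxhat = dout * gamma.reshape(shape)
    mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
    dx = inv_std.reshape(shape) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
    return dx, dgamma, dbeta


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, labels, sample_weights=None):
    """Mean (optionally weighted) negative log-likelihood and the gradient
    w.r.t. the logits feeding the softmax."""
    n = probs.shape[0]
    eps = 1e-12
    logp = -np.log(probs[np.arange(n), labels] + eps)
    if sample_weights is None:
        loss = logp.mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
    else:
        wsum = sample_weights.sum()
        loss = (sample_weights * logp).sum() / wsum
        dlogits = probs * sample_weights[:, None]
        dlogits[np.arange(n), labels] -= sample_weights
        dlogits /= wsum
    return loss, dlogits


def uniform_fan_in(rng: np.random.Generator, shape: tuple,
                   fan_in: int) -> np.ndarray:
    """U(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a name->array parameter dict."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
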