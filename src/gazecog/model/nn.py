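"""Minimal NumPy neural-network primitives with explicit backpropagation.

Only the pieces the classifier needs: "same"-padded 1-D convolution (via
im2col and BLAS matmul), non-overlapping max pooling, global average
pooling, dense layers, ReLU, a (weighted) softmax cross-entropy head, and
Adam. Every layer returns a cache for its backward pass; gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, pad: int):
    """x: (B, C, L); W: (F, C, k); symmetric zero padding -> (B, F, L_out)."""
    B, C, L = x.shape
    F, _, k = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = sliding_window_view(xp, k, axis=2)          # (B, C, L_out, k)
    L_out = cols.shape[2]
    col = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
        B * L_out, C * k)
    y = col @ W.reshape(F, C * k).T + b
    y = y.reshape(B, L_out, F).transpose(0, 2, 1)
    return y, (col, x.shape, W, pad, L_out)


def conv1d_backward(dy: np.ndarray, cache):
    col, x_shape, W, pad, L_out = cache
    B, C, L = x_shape
    F, _, k = W.shape
    dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L_out, F)
    dW = (dy2.T @ col).reshape(F, C, k)
    db = dy2.sum(axis=0)
    dcol = (dy2 @ W.reshape(F, C * k)).reshape(B, L_out, C, k)
    dxp = np.zeros((B, C, L + 2 * pad), dtype=dy.dtype)
    dcol_t = dcol.transpose(0, 2, 1, 3)                # (B, C, L_out, k)
    for j in range(k):
        dxp[:, :, j:j + L_out] += dcol_t[:, :, :, j]
    dx = dxp[:, :, pad:pad + L] if pad else dxp
    return dx, dW, db


def maxpool1d_forward(x: np.ndarray, k: int):
    """Non-overlapping max pooling (stride = kernel); trailing remainder
    samples are dropped, matching floor(L / k) output length."""
    B, C, L = x.shape
    L_out = L // k
    xt = x[:, :, :L_out * k].reshape(B, C, L_out, k)
    idx = xt.argmax(axis=3)
    y = np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]
    return y, (x.shape, k, idx)


def maxpool1d_backward(dy: np.ndarray, cache):
    x_shape, k, idx = cache
    B, C, L = x_shape
    L_out = L // k
    dxt = np.zeros((B, C, L_out, k), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, :L_out * k] = dxt.reshape(B, C, L_out * k)
    return dx


def gap_forward(x: np.ndarray):
    """Global average pooling over time: (B, C, L) -> (B, C)."""
    return x.mean(axis=2), x.shape


def gap_backward(dy: np.ndarray, x_shape):
    B, C, L = x_shape
    return np.repeat(dy[:, :, None], L, axis=2) / L


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask):
    return dy * mask


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, D); W: (F, D)."""
    return x @ W.T + b, (x, W)


def linear_backward(dy: np.ndarray, cache):
    x, W = cache
    return dy @ W, dy.T @ x, dy.sum(axis=0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray,
                 sample_weight: np.ndarray | None = None):
    """Weighted mean cross-entropy over a batch.

    Returns (loss, dlogits, per_sample_loss). ``sample_weight`` rescales each
    sample's contribution; the mean is taken over the raw batch size so that
    down-weighted samples genuinely contribute less.
    """
    B = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    per = -np.log(p[np.arange(B), labels] + eps)
    w = np.ones(B, dtype=logits.dtype) if sample_weight is None else sample_weight
    loss = float((w * per).sum() / B)
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (w / B)[:, None]
    return loss, dlogits.astype(logits.dtype), per


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
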