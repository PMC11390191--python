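"""Minimal numpy neural-network layers with exact backward passes.

Only what the four sentence classifiers need: 1-D convolution, max-pooling,
dense, LSTM (full backpropagation through time), inverted dropout, softmax
cross-entropy, and the AdaDelta optimizer (adaptive per-coordinate steps, no
learning-rate tuning).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "maxpool1d_forward",
    "maxpool1d_backward",
    "dense_forward",
    "dense_backward",
    "lstm_forward",
    "lstm_backward",
    "dropout_forward",
    "dropout_backward",
    "softmax",
    "softmax_cross_entropy",
    "relu",
    "AdaDelta",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def conv1d_forward(X, W, b, stride: int = 1):
    """1-D convolution over the time axis.

    X: (N, T, d); W: (m*d, F) for filter width m; returns (N, L, F) with
    L = (T - m) // stride + 1.
    """
    N, T, d = X.shape
    md, F = W.shape
    m = md // d
    L = (T - m) // stride + 1
    starts = np.arange(L) * stride
    # (N, L, m, d) windows -> (N, L, m*d)
    idx = starts[:, None] + np.arange(m)[None, :]
    Xc = X[:, idx, :].reshape(N, L, m * d)
    out = Xc @ W + b
    cache = (Xc, W, X.shape, idx, stride)
    return out, cache


def conv1d_backward(dout, cache):
    Xc, W, x_shape, idx, stride = cache
    N, L, F = dout.shape
    md = W.shape[0]
    d = x_shape[2]
    m = md // d
    dW = Xc.reshape(-1, md).T @ dout.reshape(-1, F)
    db = dout.sum(axis=(0, 1))
    dXc = (dout @ W.T).reshape(N, L, m, d)
    dX = np.zeros(x_shape)
    for t in range(m):
        np.add.at(dX, (slice(None), idx[:, t], slice(None)), dXc[:, :, t, :])
    return dX, dW, db


def maxpool1d_forward(X, size: int):
    """Non-overlapping max pool of width ``size`` over the time axis."""
    N, L, F = X.shape
    Lp = L // size
    Xt = X[:, : Lp * size, :].reshape(N, Lp, size, F)
    arg = Xt.argmax(axis=2)
    out = np.take_along_axis(Xt, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (arg, X.shape, size)


def maxpool1d_backward(dout, cache):
    arg, x_shape, size = cache
    N, Lp, F = dout.shape
    dXt = np.zeros((N, Lp, size, F))
    np.put_along_axis(dXt, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    dX = np.zeros(x_shape)
    dX[:, : Lp * size, :] = dXt.reshape(N, Lp * size, F)
    return dX


def dense_forward(X, W, b):
    return X @ W + b, (X, W)


def dense_backward(dout, cache):
    X, W = cache
    return dout @ W.T, X.T @ dout, dout.sum(axis=0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_forward(X, Wx, Wh, b):
    """LSTM over the full sequence.

    X: (N, T, d); Wx: (d, 4H); Wh: (H, 4H); b: (4H,); gate order i, f, o, g.
    Returns all hidden states H_all (N, T, H) plus the backward cache.
    """
    N, T, d = X.shape
    H = Wh.shape[0]
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    H_all = np.empty((N, T, H))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        a = x_t @ Wx + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        o = _sigmoid(a[:, 2 * H : 3 * H])
        g = np.tanh(a[:, 3 * H :])
        c_next = f * c + i * g
        tanh_c = np.tanh(c_next)
        h_next = o * tanh_c
        caches.append((x_t, h, c, i, f, o, g, tanh_c))
        h, c = h_next, c_next
        H_all[:, t, :] = h
    return H_all, (caches, Wx, Wh, X.shape)


def lstm_backward(dH_all, cache):
    """Backprop through time given per-step upstream gradients dH_all
    (N, T, H); steps with no upstream signal just carry zeros."""
    caches, Wx, Wh, x_shape = cache
    N, T, d = x_shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros(x_shape)
    dh_rec = np.zeros((N, H))
    dc = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, tanh_c = caches[t]
        dh = dH_all[:, t, :] + dh_rec
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        dWx += x_t.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dX[:, t, :] = da @ Wx.T
        dh_rec = da @ Wh.T
        dc = dc * f
    return dX, dWx, dWh, db


def dropout_forward(X, p: float, rng: np.random.Generator | None, train: bool):
    """Inverted dropout: at train time keep with prob 1-p and rescale."""
    if not train or p <= 0.0:
        return X, None
    mask = (rng.random(X.shape) >= p) / (1.0 - p)
    return X * mask, mask


def dropout_backward(dout, mask):
    return dout if mask is None else dout * mask


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(scores, y_idx):
    """Mean categorical cross-entropy; returns (loss, dscores)."""
    N = scores.shape[0]
    probs = softmax(scores)
    loss = -np.log(np.clip(probs[np.arange(N), y_idx], 1e-12, None)).mean()
    dscores = probs.copy()
    dscores[np.arange(N), y_idx] -= 1.0
    return loss, dscores / N


class AdaDelta:
    """AdaDelta: per-coordinate steps from running averages of squared
    gradients and squared updates; no learning rate to tune."""

    def __init__(self, rho: float = 0.95, eps: float = 1e-6) -> None:
        self.rho = rho
        self.eps = eps
        self._Eg: dict[str, np.ndarray] = {}
        self._Ex: dict[str, np.ndarray] = {}

    def update(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            if k not in self._Eg:
                self._Eg[k] = np.zeros_like(g)
                self._Ex[k] = np.zeros_like(g)
            Eg, Ex = self._Eg[k], self._Ex[k]
            Eg *= self.rho
            Eg += (1.0 - self.rho) * g * g
            step = -np.sqrt((Ex + self.eps) / (Eg + self.eps)) * g
            Ex *= self.rho
            Ex += (1.0 - self.rho) * step * step
            params[k] += step
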