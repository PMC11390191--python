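"""The four sentence-classification networks over frozen embedding matrices.

Each network maps a batch of k x d sentence matrices to class scores:

* CNN: 1-D convolution (F filters of width m, stride s, ReLU) -> max-pool
  of size 2 -> dropout -> dense softmax, with L2 regularization on the
  convolution weights.
* LSTM: recurrent cell over the k time steps -> final hidden state ->
  dropout -> dense softmax.
* BiLSTM: forward and backward LSTMs whose hidden states are combined by
  elementwise sum -> dropout -> dense softmax.
* CNN-LSTM: the CNN's pooled feature sequence feeds the LSTM.

All weights are sampled uniformly from [-0.1, 0.1]; LSTM forget-gate biases
start at 1.  Softmax cross-entropy is the loss throughout.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    conv1d_backward,
    conv1d_forward,
    dense_backward,
    dense_forward,
    dropout_backward,
    dropout_forward,
    lstm_backward,
    lstm_forward,
    maxpool1d_backward,
    maxpool1d_forward,
    relu,
)

__all__ = ["ARCHITECTURES", "make_network"]

_INIT_SCALE = 0.1


def _uniform(rng, *shape):
    return rng.uniform(-_INIT_SCALE, _INIT_SCALE, size=shape)


def _lstm_params(rng, d, H, prefix):
    b = _uniform(rng, 4 * H)
    b[H : 2 * H] = 1.0  # forget-gate bias
    return {
        f"{prefix}Wx": _uniform(rng, d, 4 * H),
        f"{prefix}Wh": _uniform(rng, H, 4 * H),
        f"{prefix}b": b,
    }


class _Base:
    """Shared plumbing: parameter dict, L2 on convolution weights."""

    conv_keys: tuple[str, ...] = ()

    def __init__(self, spec, d: int, rng: np.random.Generator) -> None:
        self.spec = spec
        self.d = d
        self.params: dict[str, np.ndarray] = {}
        self._build(rng)

    def _build(self, rng) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.5 * self.spec.l2 * sum(
            float(np.sum(self.params[k] ** 2)) for k in self.conv_keys
        )

    def add_l2_grads(self, grads: dict[str, np.ndarray]) -> None:
        for k in self.conv_keys:
            grads[k] = grads[k] + self.spec.l2 * self.params[k]


class CNN(_Base):
    conv_keys = ("conv_W",)

    def _build(self, rng) -> None:
        s = self.spec
        md = s.filter_width * self.d
        L = (s.k - s.filter_width) // s.stride + 1
        flat = (L // s.pool) * s.n_filters
        self.params = {
            "conv_W": _uniform(rng, md, s.n_filters),
            "conv_b": np.zeros(s.n_filters),
            "out_W": _uniform(rng, flat, s.n_classes),
            "out_b": np.zeros(s.n_classes),
        }

    def forward(self, X, train=False, rng=None):
        p, s = self.params, self.spec
        z, c_conv = conv1d_forward(X, p["conv_W"], p["conv_b"], s.stride)
        a = relu(z)
        pooled, c_pool = maxpool1d_forward(a, s.pool)
        flat = pooled.reshape(X.shape[0], -1)
        dropped, mask = dropout_forward(flat, s.dropout, rng, train)
        scores, c_out = dense_forward(dropped, p["out_W"], p["out_b"])
        return scores, (c_conv, z, c_pool, pooled.shape, mask, c_out)

    def backward(self, dscores, cache):
        c_conv, z, c_pool, pooled_shape, mask, c_out = cache
        dflat, dWo, dbo = dense_backward(dscores, c_out)
        dflat = dropout_backward(dflat, mask)
        dpool = dflat.reshape(pooled_shape)
        da = maxpool1d_backward(dpool, c_pool)
        dz = da * (z > 0)
        _, dWc, dbc = conv1d_backward(dz, c_conv)
        grads = {"conv_W": dWc, "conv_b": dbc, "out_W": dWo, "out_b": dbo}
        self.add_l2_grads(grads)
        return grads


class LSTMNet(_Base):
    def _build(self, rng) -> None:
        s = self.spec
        self.params = {
            **_lstm_params(rng, self.d, s.lstm_units, ""),
            "out_W": _uniform(rng, s.lstm_units, s.n_classes),
            "out_b": np.zeros(s.n_classes),
        }

    def forward(self, X, train=False, rng=None):
        p, s = self.params, self.spec
        H_all, c_lstm = lstm_forward(X, p["Wx"], p["Wh"], p["b"])
        h_last = H_all[:, -1, :]
        dropped, mask = dropout_forward(h_last, s.dropout, rng, train)
        scores, c_out = dense_forward(dropped, p["out_W"], p["out_b"])
        return scores, (c_lstm, H_all.shape, mask, c_out)

    def backward(self, dscores, cache):
        c_lstm, h_shape, mask, c_out = cache
        dh, dWo, dbo = dense_backward(dscores, c_out)
        dh = dropout_backward(dh, mask)
        dH_all = np.zeros(h_shape)
        dH_all[:, -1, :] = dh
        _, dWx, dWh, db = lstm_backward(dH_all, c_lstm)
        return {"Wx": dWx, "Wh": dWh, "b": db, "out_W": dWo, "out_b": dbo}


class BiLSTMNet(_Base):
    def _build(self, rng) -> None:
        s = self.spec
        self.params = {
            **_lstm_params(rng, self.d, s.lstm_units, "f_"),
            **_lstm_params(rng, self.d, s.lstm_units, "b_"),
            "out_W": _uniform(rng, s.lstm_units, s.n_classes),
            "out_b": np.zeros(s.n_classes),
        }

    def sequence_outputs(self, X):
        """Per-position outputs h_i = h_fwd_i + h_bwd_i (elementwise sum)."""
        p = self.params
        Hf, _ = lstm_forward(X, p["f_Wx"], p["f_Wh"], p["f_b"])
        Hb_rev, _ = lstm_forward(X[:, ::-1, :], p["b_Wx"], p["b_Wh"], p["b_b"])
        return Hf + Hb_rev[:, ::-1, :]

    def forward(self, X, train=False, rng=None):
        p, s = self.params, self.spec
        Hf, c_f = lstm_forward(X, p["f_Wx"], p["f_Wh"], p["f_b"])
        Hb, c_b = lstm_forward(X[:, ::-1, :], p["b_Wx"], p["b_Wh"], p["b_b"])
        # summed final representation: forward at position k, backward at
        # position 1 (its last processed step)
        rep = Hf[:, -1, :] + Hb[:, -1, :]
        dropped, mask = dropout_forward(rep, s.dropout, rng, train)
        scores, c_out = dense_forward(dropped, p["out_W"], p["out_b"])
        return scores, (c_f, c_b, Hf.shape, mask, c_out)

    def backward(self, dscores, cache):
        c_f, c_b, h_shape, mask, c_out = cache
        drep, dWo, dbo = dense_backward(dscores, c_out)
        drep = dropout_backward(drep, mask)
        dH = np.zeros(h_shape)
        dH[:, -1, :] = drep
        _, dWxf, dWhf, dbf = lstm_backward(dH, c_f)
        _, dWxb, dWhb, dbb = lstm_backward(dH, c_b)
        return {
            "f_Wx": dWxf,
            "f_Wh": dWhf,
            "f_b": dbf,
            "b_Wx": dWxb,
            "b_Wh": dWhb,
            "b_b": dbb,
            "out_W": dWo,
            "out_b": dbo,
        }


class CNNLSTM(_Base):
    conv_keys = ("conv_W",)

    def _build(self, rng) -> None:
        s = self.spec
        self.params = {
            "conv_W": _uniform(rng, s.filter_width * self.d, s.n_filters),
            "conv_b": np.zeros(s.n_filters),
            **_lstm_params(rng, s.n_filters, s.lstm_units, ""),
            "out_W": _uniform(rng, s.lstm_units, s.n_classes),
            "out_b": np.zeros(s.n_classes),
        }

    def forward(self, X, train=False, rng=None):
        p, s = self.params, self.spec
        z, c_conv = conv1d_forward(X, p["conv_W"], p["conv_b"], s.stride)
        a = relu(z)
        pooled, c_pool = maxpool1d_forward(a, s.pool)
        H_all, c_lstm = lstm_forward(pooled, p["Wx"], p["Wh"], p["b"])
        h_last = H_all[:, -1, :]
        dropped, mask = dropout_forward(h_last, s.dropout, rng, train)
        scores, c_out = dense_forward(dropped, p["out_W"], p["out_b"])
        return scores, (c_conv, z, c_pool, c_lstm, H_all.shape, mask, c_out)

    def backward(self, dscores, cache):
        c_conv, z, c_pool, c_lstm, h_shape, mask, c_out = cache
        dh, dWo, dbo = dense_backward(dscores, c_out)
        dh = dropout_backward(dh, mask)
        dH_all = np.zeros(h_shape)
        dH_all[:, -1, :] = dh
        dpooled, dWx, dWh, db = lstm_backward(dH_all, c_lstm)
        da = maxpool1d_backward(dpooled, c_pool)
        dz = da * (z > 0)
        _, dWc, dbc = conv1d_backward(dz, c_conv)
        grads = {
            "conv_W": dWc,
            "conv_b": dbc,
            "Wx": dWx,
            "Wh": dWh,
            "b": db,
            "out_W": dWo,
            "out_b": dbo,
        }
        self.add_l2_grads(grads)
        return grads


ARCHITECTURES = {
    "cnn": CNN,
    "lstm": LSTMNet,
    "bilstm": BiLSTMNet,
    "cnnlstm": CNNLSTM,
    "cnn-lstm": CNNLSTM,
    "cnn_lstm": CNNLSTM,
}


def make_network(spec, d: int, rng: np.random.Generator):
    arch = spec.arch.lower()
    if arch not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {spec.arch!r}; expected one of "
            f"{sorted(set(ARCHITECTURES))}"
        )
    return ARCHITECTURES[arch](spec, d, rng)
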