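"""Minimal recurrent neural-network primitives with analytic gradients.

The sequence model at the heart of the package needs only three building
blocks — an LSTM layer, a dense (linear) layer and the Adam optimizer — so
they are implemented directly on NumPy arrays.  Every layer caches its forward
activations and exposes ``backward``, which returns the gradient with respect
to its input and stores parameter gradients in ``.grads``.  Correctness is
pinned down by finite-difference gradient checks in the test suite.

Gate convention for the LSTM cell (order i, f, g, o within the stacked
weight matrices)::

    a_t            = x_t W_x + h_{t-1} W_h + b
    i_t, f_t, o_t  = sigmoid of their slices of a_t
    g_t            = tanh of its slice
    c_t            = f_t * c_{t-1} + i_t * g_t
    h_t            = o_t * tanh(c_t)

All computation is float64 and single-threaded NumPy, so forward and backward
passes are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "LSTMLayer", "DenseLayer", "Adam"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # exp(-x) overflows to inf for very negative x, giving the correct limit 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """Block-orthogonal init for recurrent kernels (one block per gate)."""
    blocks = []
    for _ in range(n_cols // n_rows):
        q, r = np.linalg.qr(rng.standard_normal((n_rows, n_rows)))
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class LSTMLayer:
    """Single LSTM layer processing full sequences, batch-first (B, T, D)."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        H = hidden_dim
        self.Wx = _glorot(rng, (input_dim, 4 * H))
        self.Wh = _orthogonal(rng, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
        self.grads = {}
        self._cache = None

    @property
    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden_dim
        A_in = x @ self.Wx + self.b  # input contribution for every step at once
        I = np.empty((B, T, H)); F = np.empty((B, T, H))
        G = np.empty((B, T, H)); O = np.empty((B, T, H))
        C = np.empty((B, T, H)); TC = np.empty((B, T, H))
        Hprev = np.empty((B, T, H)); Cprev = np.empty((B, T, H))
        h = np.zeros((B, H)); c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        for t in range(T):
            Hprev[:, t] = h
            Cprev[:, t] = c
            a = A_in[:, t] + h @ self.Wh
            sif = sigmoid(a[:, : 2 * H])
            i, f = sif[:, :H], sif[:, H:]
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
            C[:, t], TC[:, t] = c, tc
            hs[:, t] = h
        self._cache = (x, I, F, G, O, C, TC, Hprev, Cprev)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, I, F, G, O, C, TC, Hprev, Cprev = self._cache
        B, T, H = dhs.shape
        dA = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dhs[:, t] + dh_next
            dc = dc_next + dh * O[:, t] * (1.0 - TC[:, t] ** 2)
            dA[:, t, :H] = dc * G[:, t] * I[:, t] * (1.0 - I[:, t])
            dA[:, t, H : 2 * H] = dc * Cprev[:, t] * F[:, t] * (1.0 - F[:, t])
            dA[:, t, 2 * H : 3 * H] = dc * I[:, t] * (1.0 - G[:, t] ** 2)
            dA[:, t, 3 * H :] = dh * TC[:, t] * O[:, t] * (1.0 - O[:, t])
            dh_next = dA[:, t] @ self.Wh.T
            dc_next = dc * F[:, t]
        flat_dA = dA.reshape(B * T, 4 * H)
        self.grads = {
            "Wx": x.reshape(B * T, -1).T @ flat_dA,
            "Wh": Hprev.reshape(B * T, H).T @ flat_dA,
            "b": flat_dA.sum(axis=0),
        }
        return dA @ self.Wx.T


class DenseLayer:
    """Affine layer applied to the last axis (works time-distributed)."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, (input_dim, output_dim))
        self.b = np.zeros(output_dim)
        self.grads = {}
        self._x = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.grads = {"W": flat_x.T @ flat_dy, "b": flat_dy.sum(axis=0)}
        return dy @ self.W.T


class Adam:
    """Adam with the classic inverse-time learning-rate decay lr/(1 + decay·t)."""

    def __init__(self, layers, learning_rate=0.001, decay=0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = list(layers)
        self.lr = learning_rate
        self.decay = decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]

    def step(self) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * (self.t - 1))
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g * g
                p -= lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
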