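"""LSTM variational autoencoder over daily 48-slot binary motion sequences.

Each day is a length-48 binary sequence.  A two-layer LSTM encoder reads the
sequence and two linear heads map its final hidden state to the mean and
log-variance of a diagonal Gaussian posterior q(z|x) over a low-dimensional
latent (7 by default).  A latent sample z = mu + sigma * eps (the
reparameterization trick) is repeated across the 48 steps and fed to a
two-layer LSTM decoder whose per-step sigmoid head outputs the reconstruction
probability of motion in every slot.

The training objective is the negative evidence lower bound:

    L = BCE(x, x_hat) + KL( N(mu, sigma^2) || N(0, I) ) + lambda * |W_enc|_1

with the binary cross-entropy averaged over the 48 slots, the KL in closed
form, and an L1 penalty on the encoder LSTM weight matrices.  Optimization is
Adam with mini-batches of 7 days over 200 epochs by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .nn import Adam, DenseLayer, LSTMLayer, sigmoid
from .preprocess import DayMatrix
from .simulate import SLOTS_PER_DAY

__all__ = [
    "VaeConfig",
    "LatentStats",
    "LossBreakdown",
    "LstmVae",
    "encode",
    "sample_latent",
    "decode",
    "kl_term",
    "reconstruction_term",
    "total_loss",
    "train",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-7


@dataclass(frozen=True)
class VaeConfig:
    """Hyperparameters; the defaults are the reference study configuration."""

    n_hidden_units: int = 100
    n_recurrent_layers_encoder: int = 2
    n_recurrent_layers_decoder: int = 2
    latent_dim: int = 7
    hidden_activation: str = "tanh"
    l1_weight: float = 0.001
    batch_size: int = 7
    epochs: int = 200
    optimizer: str = "adam"
    learning_rate: float = 0.001
    lr_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hidden_units", "n_recurrent_layers_encoder",
                     "n_recurrent_layers_decoder", "latent_dim", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.l1_weight < 0 or self.lr_decay < 0:
            raise ValueError("l1_weight and lr_decay must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_activation != "tanh":
            raise ValueError("only the tanh hidden activation is supported")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class LatentStats:
    """Gaussian posterior parameters: mean and log-variance per latent dim."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have equal shapes")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_var).all()):
            raise ValueError("latent statistics must be finite")


@dataclass(frozen=True)
class LossBreakdown:
    reconstruction: float
    kl: float
    l1_penalty: float
    total: float


def _as_batch(x, name="day") -> tuple[np.ndarray, bool]:
    """Coerce (48,), (48,1), (B,48) or (B,48,1) binary input to (B,48) float."""
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1 or (arr.ndim == 2 and arr.shape == (SLOTS_PER_DAY, 1))
    if arr.ndim == 2 and arr.shape == (SLOTS_PER_DAY, 1):
        arr = arr[:, 0]
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.ndim != 2 or arr.shape[1] != SLOTS_PER_DAY:
        raise ValueError(f"{name} must have {SLOTS_PER_DAY} slots, got shape {np.shape(x)}")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary")
    return arr, single


class LstmVae:
    """Encoder/decoder pair with explicit forward and backward passes."""

    def __init__(self, config: VaeConfig, seq_len: int = SLOTS_PER_DAY):
        self.config = config
        self.seq_len = seq_len
        ss = np.random.SeedSequence(config.seed)
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        H, L = config.n_hidden_units, config.latent_dim
        self.enc_lstm = []
        d = 1
        for _ in range(config.n_recurrent_layers_encoder):
            self.enc_lstm.append(LSTMLayer(d, H, init_rng))
            d = H
        self.fc_mu = DenseLayer(H, L, init_rng)
        self.fc_log_var = DenseLayer(H, L, init_rng)
        self.dec_lstm = []
        d = L
        for _ in range(config.n_recurrent_layers_decoder):
            self.dec_lstm.append(LSTMLayer(d, H, init_rng))
            d = H
        self.fc_out = DenseLayer(H, 1, init_rng)
        self.trained = False

    # -- layer bookkeeping -------------------------------------------------

    @property
    def layers(self):
        return [*self.enc_lstm, self.fc_mu, self.fc_log_var, *self.dec_lstm, self.fc_out]

    def l1_penalty(self) -> float:
        """L1 norm of the encoder LSTM weight matrices, scaled by l1_weight."""
        if self.config.l1_weight == 0:
            return 0.0
        s = sum(np.abs(lay.Wx).sum() + np.abs(lay.Wh).sum() for lay in self.enc_lstm)
        return float(self.config.l1_weight * s)

    # -- forward passes ----------------------------------------------------

    def encode(self, day) -> LatentStats:
        """Posterior Gaussian parameters for one day or a batch of days."""
        x, single = _as_batch(day)
        if x.shape[1] != self.seq_len:
            raise ValueError(f"expected sequences of length {self.seq_len}")
        h = x[:, :, None]
        for lay in self.enc_lstm:
            h = lay.forward(h)
        h_last = h[:, -1]
        mu = self.fc_mu.forward(h_last)
        log_var = self.fc_log_var.forward(h_last)
        if single:
            mu, log_var = mu[0], log_var[0]
        return LatentStats(mu=mu, log_var=log_var)

    def decode(self, z) -> np.ndarray:
        """Per-slot motion probabilities for latent vector(s) z."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        if single:
            z = z[None, :]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent vector must have length {self.config.latent_dim}, got {z.shape[1]}"
            )
        probs = sigmoid(self._decode_logits(z))
        return probs[0] if single else probs

    def _decode_logits(self, z: np.ndarray) -> np.ndarray:
        h = np.repeat(z[:, None, :], self.seq_len, axis=1)
        for lay in self.dec_lstm:
            h = lay.forward(h)
        return self.fc_out.forward(h)[:, :, 0]

    def reconstruct(self, days, mode: str = "mean",
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Reconstruction probabilities; ``mode`` is 'mean' (z = mu) or 'sample'."""
        stats = self.encode(days)
        single = stats.mu.ndim == 1
        mu = np.atleast_2d(stats.mu)
        lv = np.atleast_2d(stats.log_var)
        if mode == "mean":
            z = mu
        elif mode == "sample":
            if rng is None:
                rng = np.random.default_rng(0)
            z = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        probs = self.decode(z)
        return probs[0] if single else probs

    # -- one training step ---------------------------------------------------

    def _step(self, x: np.ndarray, rng: np.random.Generator, optimizer: Adam):
        """Forward + backward + parameter update on a (B, 48) binary batch."""
        cfg = self.config
        B, T = x.shape
        h = x[:, :, None]
        for lay in self.enc_lstm:
            h = lay.forward(h)
        h_last = h[:, -1]
        mu = self.fc_mu.forward(h_last)
        lv = self.fc_log_var.forward(h_last)
        eps = rng.standard_normal(mu.shape)
        sig = np.exp(0.5 * lv)
        z = mu + sig * eps
        logits = self._decode_logits(z)
        p = sigmoid(logits)

        # numerically stable BCE from logits: softplus(a) - x*a
        bce = np.logaddexp(0.0, logits) - x * logits
        recon = float(bce.mean(axis=1).mean())
        kl_per = -0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv), axis=1)
        kl = float(kl_per.mean())
        l1 = self.l1_penalty()
        total = recon + kl + l1

        # --- backward ---
        dlogits = (p - x) / (B * T)
        dh_dec = self.fc_out.backward(dlogits[:, :, None])
        for lay in reversed(self.dec_lstm):
            dh_dec = lay.backward(dh_dec)
        dz = dh_dec.sum(axis=1)
        dmu = dz + mu / B
        dlv = dz * eps * 0.5 * sig + 0.5 * (np.exp(lv) - 1.0) / B
        dh_last = self.fc_mu.backward(dmu) + self.fc_log_var.backward(dlv)
        dh_enc = np.zeros((B, T, self.config.n_hidden_units))
        dh_enc[:, -1] = dh_last
        for lay in reversed(self.enc_lstm):
            dh_enc = lay.backward(dh_enc)
        if cfg.l1_weight:
            for lay in self.enc_lstm:
                lay.grads["Wx"] += cfg.l1_weight * np.sign(lay.Wx)
                lay.grads["Wh"] += cfg.l1_weight * np.sign(lay.Wh)
        optimizer.step()
        return recon, kl, l1, total


# ---------------------------------------------------------------------------
# Functional surface


def encode(day, model: LstmVae) -> LatentStats:
    return model.encode(day)


def sample_latent(stats: LatentStats, seed: Union[int, np.random.Generator]) -> np.ndarray:
    """Reparameterized draw z = mu + exp(log_var/2) * eps, eps ~ N(0, I)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(stats.mu.shape)
    return stats.mu + np.exp(0.5 * stats.log_var) * eps


def decode(z, model: LstmVae) -> np.ndarray:
    return model.decode(z)


def kl_term(stats: LatentStats):
    """Closed-form KL( N(mu, sigma^2) || N(0, I) ), summed over latent dims.

    Returns a scalar for a single stats vector, a per-sample array for a
    batch.  Always non-negative; zero exactly at the standard-normal posterior.
    """
    mu, lv = stats.mu, stats.log_var
    axis = -1
    val = -0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv), axis=axis)
    return float(val) if np.ndim(val) == 0 else val


def reconstruction_term(x, x_hat):
    """Mean per-slot binary cross-entropy between a day and its reconstruction."""
    xb, single = _as_batch(x, name="x")
    xh = np.asarray(x_hat, dtype=float)
    if xh.ndim == 1:
        xh = xh[None, :]
    if xh.shape != xb.shape:
        raise ValueError(f"x and x_hat shapes differ: {np.shape(x)} vs {np.shape(x_hat)}")
    p = np.clip(xh, PROB_CLIP, 1.0 - PROB_CLIP)
    bce = -(xb * np.log(p) + (1.0 - xb) * np.log(1.0 - p)).mean(axis=1)
    return float(bce[0]) if single else bce


def total_loss(x, x_hat, stats: LatentStats, model: LstmVae) -> LossBreakdown:
    """Reconstruction + KL + L1 penalty, with the additive breakdown reported."""
    recon = reconstruction_term(x, x_hat)
    kl = kl_term(stats)
    recon = float(np.mean(recon))
    kl = float(np.mean(kl))
    l1 = model.l1_penalty()
    return LossBreakdown(reconstruction=recon, kl=kl, l1_penalty=l1,
                         total=recon + kl + l1)


def train(train_dm: Union[DayMatrix, np.ndarray], config: VaeConfig):
    """Train a fresh model on a day matrix; returns (model, per-epoch history).

    Mini-batches are reshuffled every epoch from the config seed (the last
    short batch is kept), so the run is exactly reproducible.  History rows
    hold the epoch means of each loss component.  Divergence (a non-finite
    loss) aborts with the epoch named.
    """
    X = train_dm.slots if isinstance(train_dm, DayMatrix) else np.asarray(train_dm)
    if X.ndim == 3:
        X = X[:, :, 0]
    X = X.astype(float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("training set is empty")

    model = LstmVae(config)
    ss = np.random.SeedSequence(config.seed)
    _, train_ss = ss.spawn(2)
    rng = np.random.default_rng(train_ss)
    optimizer = Adam(model.layers, learning_rate=config.learning_rate,
                     decay=config.lr_decay)

    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            parts = model._step(batch, rng, optimizer)
            sums += parts
            n_batches += 1
        means = sums / n_batches
        if not np.isfinite(means).all():
            raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch + 1}")
        history.append(
            {"epoch": epoch + 1, "reconstruction": means[0], "kl": means[1],
             "l1": means[2], "total": means[3]}
        )
        logger.debug("epoch %d: total=%.5f recon=%.5f kl=%.5f",
                     epoch + 1, means[3], means[0], means[1])
    model.trained = config.epochs > 0
    cols = ["epoch", "reconstruction", "kl", "l1", "total"]
    return model, pd.DataFrame(history, columns=cols)


# ---------------------------------------------------------------------------
# Checkpointing: single .npz archive with the config embedded as JSON


def save_model(model: LstmVae, path) -> None:
    arrays = {}
    for i, lay in enumerate(model.layers):
        for k, v in lay.params.items():
            arrays[f"layer{i}_{k}"] = v
    meta = {"config": asdict(model.config), "seq_len": model.seq_len,
            "trained": model.trained}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> LstmVae:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = LstmVae(VaeConfig(**meta["config"]), seq_len=meta["seq_len"])
        for i, lay in enumerate(model.layers):
            for k in lay.params:
                lay.params[k][...] = data[f"layer{i}_{k}"]
        model.trained = meta["trained"]
    return model
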