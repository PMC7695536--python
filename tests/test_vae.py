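"""Sequence-model mechanics: posteriors, sampling, losses, gradients, training."""

import numpy as np
import pytest

from habitmon import (
    LatentStats,
    LstmVae,
    VaeConfig,
    decode,
    encode,
    kl_term,
    reconstruction_term,
    sample_latent,
    total_loss,
)
from habitmon.nn import sigmoid
from habitmon.vae import load_model, save_model, train
from conftest import household_a_pattern


def make_day(seed=0):
    return np.random.default_rng(seed).integers(0, 2, 48)


class TestEncodeDecode:
    def test_forward_pass_is_deterministic(self):
        model = LstmVae(VaeConfig(seed=1))
        day = make_day()
        a, b = model.encode(day), model.encode(day)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.log_var, b.log_var)

    def test_latent_dimension_is_seven_by_default(self):
        stats = encode(make_day(), LstmVae(VaeConfig()))
        assert stats.mu.shape == (7,) and stats.log_var.shape == (7,)

    def test_decode_contract(self):
        model = LstmVae(VaeConfig(seed=2))
        probs = decode(np.zeros(7), model)
        assert probs.shape == (48,)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_input_validation(self):
        model = LstmVae(VaeConfig())
        with pytest.raises(ValueError):
            model.encode(np.zeros(47))
        with pytest.raises(ValueError):
            model.encode(np.full(48, 2))
        with pytest.raises(ValueError):
            model.decode(np.zeros(6))

    def test_distinct_inputs_get_distinct_posteriors(self, tiny_cfg):
        """After training on a two-pattern toy set, the posteriors separate."""
        X = np.concatenate([np.zeros((10, 48)), np.ones((10, 48))])
        model, _ = train(X, tiny_cfg)
        mu0 = model.encode(np.zeros(48)).mu
        mu1 = model.encode(np.ones(48)).mu
        assert np.linalg.norm(mu1 - mu0) > 0


class TestSampleLatent:
    def test_degenerate_variance_returns_mean(self):
        stats = LatentStats(mu=np.arange(4.0), log_var=np.full(4, -700.0))
        assert np.allclose(sample_latent(stats, 0), stats.mu)

    def test_standard_normal_moments(self):
        stats = LatentStats(mu=np.zeros(3), log_var=np.zeros(3))
        rng = np.random.default_rng(1)
        draws = np.array([sample_latent(stats, rng) for _ in range(10_000)])
        assert np.abs(draws.mean(axis=0)).max() < 3 / np.sqrt(10_000)
        assert np.abs(draws.var(axis=0) - 1.0).max() < 0.05

    def test_seed_reproducibility(self):
        stats = LatentStats(mu=np.ones(5), log_var=np.zeros(5))
        assert np.array_equal(sample_latent(stats, 7), sample_latent(stats, 7))


class TestLossTerms:
    def test_kl_zero_at_standard_normal(self):
        assert kl_term(LatentStats(np.zeros(7), np.zeros(7))) == 0.0

    def test_kl_closed_form_unit_mean(self):
        stats = LatentStats(np.eye(7)[0], np.zeros(7))
        assert kl_term(stats) == pytest.approx(0.5)

    def test_kl_nonnegative_and_zero_only_at_prior(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            stats = LatentStats(rng.normal(size=7), rng.normal(size=7))
            assert kl_term(stats) > 0

    def test_kl_matches_monte_carlo(self):
        """Closed form vs E_q[log q - log p] estimated from 2e5 draws."""
        rng = np.random.default_rng(9)
        mu = rng.uniform(-2, 2, 4)
        lv = rng.uniform(-1, 1, 4)
        eps = rng.standard_normal((200_000, 4))
        z = mu + np.exp(0.5 * lv) * eps
        log_q = -0.5 * (np.sum(lv) + (eps**2).sum(axis=1) + 4 * np.log(2 * np.pi))
        log_p = -0.5 * ((z**2).sum(axis=1) + 4 * np.log(2 * np.pi))
        mc = (log_q - log_p).mean()
        assert kl_term(LatentStats(mu, lv)) == pytest.approx(mc, rel=0.02)

    def test_bce_closed_forms(self):
        x = make_day(5)
        assert reconstruction_term(x, np.full(48, 0.5)) == pytest.approx(np.log(2))
        ones = np.ones(48)
        assert reconstruction_term(ones, np.full(48, 0.9)) == pytest.approx(-np.log(0.9))
        near_perfect = np.clip(x.astype(float), 1e-7, 1 - 1e-7)
        assert reconstruction_term(x, near_perfect) < 1e-5

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_term(make_day(), np.full(24, 0.5))

    def test_total_loss_is_additive(self):
        model = LstmVae(VaeConfig(seed=4))
        x = make_day(2)
        stats = model.encode(x)
        x_hat = model.decode(stats.mu)
        lb = total_loss(x, x_hat, stats, model)
        assert lb.total == pytest.approx(lb.reconstruction + lb.kl + lb.l1_penalty, abs=1e-6)
        zero_l1 = LstmVae(VaeConfig(l1_weight=0.0, seed=4))
        lb0 = total_loss(x, x_hat, stats, zero_l1)
        assert lb0.total == pytest.approx(lb0.reconstruction + lb0.kl)
        assert lb0.l1_penalty == 0.0


def test_analytic_gradients_match_finite_differences():
    """Backprop through encoder, reparameterization and decoder is exact."""
    cfg = VaeConfig(n_hidden_units=6, latent_dim=3, l1_weight=0.0, seed=3)
    model = LstmVae(cfg, seq_len=5)
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, (4, 5)).astype(float)
    eps = rng.standard_normal((4, 3))

    def loss_at():
        h = x[:, :, None]
        for lay in model.enc_lstm:
            h = lay.forward(h)
        hl = h[:, -1]
        mu = model.fc_mu.forward(hl)
        lv = model.fc_log_var.forward(hl)
        z = mu + np.exp(0.5 * lv) * eps
        logits = model._decode_logits(z)
        bce = np.logaddexp(0.0, logits) - x * logits
        kl = (-0.5 * np.sum(1 + lv - mu**2 - np.exp(lv), axis=1)).mean()
        return bce.mean(axis=1).mean() + kl

    # analytic pass (mirrors the training step, without the optimizer update)
    B, T = x.shape
    h = x[:, :, None]
    for lay in model.enc_lstm:
        h = lay.forward(h)
    hl = h[:, -1]
    mu = model.fc_mu.forward(hl)
    lv = model.fc_log_var.forward(hl)
    sig = np.exp(0.5 * lv)
    logits = model._decode_logits(mu + sig * eps)
    p = sigmoid(logits)
    dlogits = (p - x) / (B * T)
    dh_dec = model.fc_out.backward(dlogits[:, :, None])
    for lay in reversed(model.dec_lstm):
        dh_dec = lay.backward(dh_dec)
    dz = dh_dec.sum(axis=1)
    dmu = dz + mu / B
    dlv = dz * eps * 0.5 * sig + 0.5 * (np.exp(lv) - 1.0) / B
    dhl = model.fc_mu.backward(dmu) + model.fc_log_var.backward(dlv)
    dh_enc = np.zeros((B, T, cfg.n_hidden_units))
    dh_enc[:, -1] = dhl
    for lay in reversed(model.enc_lstm):
        dh_enc = lay.backward(dh_enc)

    step = 1e-6
    check_rng = np.random.default_rng(11)
    for lay in model.layers:
        for k, P in lay.params.items():
            flat = check_rng.integers(0, P.size, 4)
            for i in flat:
                idx = np.unravel_index(i, P.shape)
                orig = P[idx]
                P[idx] = orig + step
                lp = loss_at()
                P[idx] = orig - step
                lm = loss_at()
                P[idx] = orig
                numeric = (lp - lm) / (2 * step)
                assert lay.grads[k][idx] == pytest.approx(numeric, rel=1e-3, abs=1e-9)


class TestTraining:
    def test_zero_epochs_is_a_no_op(self):
        X = np.tile(make_day(1), (10, 1))
        cfg = VaeConfig(n_hidden_units=8, latent_dim=2, epochs=0, seed=6)
        model, history = train(X, cfg)
        assert history.empty and not model.trained
        fresh = LstmVae(cfg)
        for a, b in zip(model.layers, fresh.layers):
            for k in a.params:
                assert np.array_equal(a.params[k], b.params[k])

    def test_seed_reproducibility(self, tiny_cfg):
        X = np.random.default_rng(2).integers(0, 2, (20, 48))
        h1 = train(X, tiny_cfg)[1]
        h2 = train(X, tiny_cfg)[1]
        assert h1["total"].iloc[-1] == pytest.approx(h2["total"].iloc[-1], abs=1e-6)

    def test_loss_decreases_and_history_complete(self, overfit_model):
        _, history = overfit_model
        assert len(history) == 50
        assert history["total"].iloc[-1] <= history["total"].iloc[0]
        smoothed = history["total"].rolling(5).mean().dropna().to_numpy()
        assert (np.diff(smoothed) <= 1e-3).mean() > 0.9  # near-monotone descent

    def test_overfit_single_pattern(self, overfit_model, overfit_pattern):
        model, history = overfit_model
        assert history["reconstruction"].iloc[-1] < 0.1
        recon = model.reconstruct(overfit_pattern.astype(float), mode="mean")
        assert np.array_equal((recon >= 0.5).astype(int), overfit_pattern)

    def test_history_additivity(self, overfit_model):
        _, history = overfit_model
        total = history["reconstruction"] + history["kl"] + history["l1"]
        assert np.allclose(total, history["total"], atol=1e-9)


def test_checkpoint_round_trip(tmp_path, tiny_cfg):
    X = np.tile(household_a_pattern(), (10, 1))
    model, _ = train(X, tiny_cfg)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.trained
    day = household_a_pattern().astype(float)
    assert np.array_equal(model.reconstruct(day, mode="mean"),
                          back.reconstruct(day, mode="mean"))


@pytest.mark.parametrize("kwargs", [
    {"latent_dim": 0}, {"batch_size": 0}, {"learning_rate": 0.0},
    {"l1_weight": -1e-3}, {"hidden_activation": "relu"}, {"optimizer": "sgd"},
])
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        VaeConfig(**kwargs)
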