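"""Shared fixtures: synthetic households and the two expensive trained models.

The two model fixtures are session-scoped because LSTM training dominates the
suite's runtime; every test that needs a trained model reuses them.
"""

import numpy as np
import pytest

from habitmon import HouseholdSpec, VaeConfig, build_day_matrix, generate_household
from habitmon.vae import train


def household_a_pattern() -> np.ndarray:
    """Binary day template: motion from 05:30 to 22:30 (slots 11..44)."""
    pattern = np.zeros(48, dtype=int)
    pattern[11:45] = 1
    return pattern


@pytest.fixture(scope="session")
def overfit_pattern():
    return household_a_pattern()


@pytest.fixture(scope="session")
def overfit_model(overfit_pattern):
    """Model overfit to 50 copies of a single day pattern (50 epochs)."""
    X = np.tile(overfit_pattern, (50, 1))
    model, history = train(X, VaeConfig(epochs=50, seed=42))
    return model, history


@pytest.fixture(scope="session")
def anomaly_case():
    """Noiseless 365-day household with 30 absence-mode days and its trained model.

    Training uses the full observed year (anomalies included, as an
    unsupervised detector would see them) at 50 epochs.
    """
    rng = np.random.default_rng(7)
    anomaly_days = frozenset(int(d) for d in rng.choice(365, 30, replace=False))
    spec = HouseholdSpec(
        p_fire_active=1.0,
        p_fire_idle=0.0,
        n_days=365,
        anomaly_days=anomaly_days,
        anomaly_mode="absence",
        seed=11,
    )
    panel = generate_household(spec)
    dm = build_day_matrix(panel)
    model, _ = train(dm, VaeConfig(epochs=50, seed=5))
    return {"spec": spec, "panel": panel, "dm": dm,
            "labels": panel.anomaly_labels, "model": model}


@pytest.fixture
def tiny_cfg():
    """Small architecture for cheap unit-level training runs."""
    return VaeConfig(n_hidden_units=12, latent_dim=3, epochs=10, seed=0)
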