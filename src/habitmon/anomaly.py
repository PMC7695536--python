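"""Reconstruction-loss anomaly scoring and the median+IQR flagging rule.

A day's anomaly score is the model's reconstruction loss for that day: the
mean per-slot binary cross-entropy between the observed 48-slot sequence and
its stochastic reconstruction.  Days whose score reaches

    median(scores) + IQR(scores),   IQR = 75th − 25th percentile

are flagged anomalous (the comparison is inclusive).  Per-household validation
mirrors a Table-1-style report: abnormal-day counts, mean loss, ROC AUC of the
reconstruction probabilities against the observed slot values, and how many
flagged days fall on weekends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .preprocess import DayMatrix
from .simulate import WEEKEND_DOWS
from .vae import LstmVae, reconstruction_term

__all__ = [
    "AnomalyReport",
    "score_days",
    "anomaly_threshold",
    "flag_anomalies",
    "validation_auc",
    "summarize_household",
    "write_report_csv",
    "write_daily_csv",
]


@dataclass
class AnomalyReport:
    """Per-household anomaly summary (one Table-1-style row plus detail)."""

    household_id: str
    dates: pd.DatetimeIndex
    scores: np.ndarray
    threshold: float
    flags: np.ndarray
    mean_loss: float
    auc: Optional[float]
    n_abnormal: int
    n_abnormal_weekend: int
    n_observed: int

    def __post_init__(self) -> None:
        if not (len(self.dates) == len(self.scores) == len(self.flags) == self.n_observed):
            raise ValueError("per-day vectors misaligned")
        if not np.array_equal(self.flags, (self.scores >= self.threshold).astype(int)):
            raise ValueError("flags inconsistent with threshold")
        if self.n_abnormal != int(self.flags.sum()) or self.n_abnormal_weekend > self.n_abnormal:
            raise ValueError("abnormal-day counts inconsistent")


def _require_trained(model: LstmVae) -> None:
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")


def score_days(model: LstmVae, dm: DayMatrix, seed: int = 0, n_mc: int = 1) -> np.ndarray:
    """Reconstruction-loss score per day, via ``n_mc`` posterior samples.

    Each day is encoded, the latent is sampled (reparameterized) and decoded,
    and the mean per-slot binary cross-entropy is averaged over the samples.
    Deterministic under ``seed``.
    """
    _require_trained(model)
    if dm.n_days == 0:
        return np.zeros(0)
    rng = np.random.default_rng(seed)
    X = dm.slots.astype(float)
    scores = np.zeros(dm.n_days)
    for _ in range(n_mc):
        probs = model.reconstruct(X, mode="sample", rng=rng)
        scores += reconstruction_term(X, probs)
    return scores / n_mc


def anomaly_threshold(scores) -> float:
    """median + (P75 − P25) of the scores, linear-interpolation quantiles."""
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 scores to estimate median and IQR")
    q25, q50, q75 = np.percentile(s, [25, 50, 75])
    return float(q50 + (q75 - q25))


def flag_anomalies(scores, threshold: float) -> np.ndarray:
    """1 where score >= threshold (the rule is inclusive), else 0."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def validation_auc(model: LstmVae, validation_dm: DayMatrix, seed: int = 0) -> Optional[float]:
    """ROC AUC over all (day, slot) pairs: reconstruction probability vs state.

    Measures whether the model places high motion probability on the slots
    where motion was actually observed.  Returns None when the validation
    slots are single-class (AUC undefined).
    """
    _require_trained(model)
    if validation_dm.n_days == 0:
        raise ValueError("validation set is empty")
    X = validation_dm.slots.astype(float)
    rng = np.random.default_rng(seed)
    probs = model.reconstruct(X, mode="sample", rng=rng)
    labels = X.ravel()
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, probs.ravel()))


def summarize_household(
    household_id: str,
    dates: pd.DatetimeIndex,
    scores: np.ndarray,
    day_of_week: np.ndarray,
    auc: Optional[float] = None,
    threshold: Optional[float] = None,
) -> AnomalyReport:
    """Assemble the per-household report from aligned per-day vectors."""
    scores = np.asarray(scores, dtype=float)
    day_of_week = np.asarray(day_of_week)
    if not (len(dates) == len(scores) == len(day_of_week)):
        raise ValueError("dates, scores and day_of_week must be aligned")
    if threshold is None:
        threshold = anomaly_threshold(scores)
    flags = flag_anomalies(scores, threshold)
    weekend = np.isin(day_of_week, WEEKEND_DOWS)
    return AnomalyReport(
        household_id=household_id,
        dates=dates,
        scores=scores,
        threshold=float(threshold),
        flags=flags,
        mean_loss=float(scores.mean()),
        auc=auc,
        n_abnormal=int(flags.sum()),
        n_abnormal_weekend=int(flags[weekend].sum()),
        n_observed=len(scores),
    )


def write_report_csv(reports, path) -> pd.DataFrame:
    """Cohort report: one row per household, Table-1-style columns."""
    df = pd.DataFrame(
        {
            "household_id": [r.household_id for r in reports],
            "abnormal_days": [r.n_abnormal for r in reports],
            "total_observed_days": [r.n_observed for r in reports],
            "loss": [round(r.mean_loss, 6) for r in reports],
            "auc": [None if r.auc is None else round(r.auc, 6) for r in reports],
            "abnormal_weekend": [r.n_abnormal_weekend for r in reports],
        }
    )
    df.to_csv(path, index=False)
    return df


def write_daily_csv(report: AnomalyReport, path) -> None:
    pd.DataFrame(
        {
            "date": report.dates.strftime("%Y-%m-%d"),
            "score": np.round(report.scores, 6),
            "flag": report.flags,
        }
    ).to_csv(path, index=False)
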