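"""Binarization of 5-minute sensor streams into daily 48-slot motion sequences.

A household's day is summarised as 48 half-hour *motion states*.  A half-hour
window is motion-positive when the summed sensor activations over its six
5-minute steps reach 4 — equivalently, one sensor active for 20 minutes, or
four sensors active for one step each.  Days with incomplete coverage are
dropped, and cohort inclusion criteria (minimum sensor count, minimum days
online, maximum occupants) filter the household manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import SLOTS_PER_DAY, STEPS_PER_DAY, STEPS_PER_SLOT, SensorPanel

__all__ = [
    "DayMatrix",
    "InclusionCriteria",
    "motion_state",
    "build_day_matrix",
    "apply_inclusion",
    "split_train_test",
    "write_day_matrix_csv",
    "read_day_matrix_csv",
]

logger = logging.getLogger(__name__)

MOTION_SUM_THRESHOLD = 4


@dataclass
class DayMatrix:
    """Stack of independent daily 48-slot binary motion sequences.

    ``X`` has shape ``(n_days, 48, 1)``: one row per complete calendar day,
    one binary motion state per half-hour slot.
    """

    household_id: str
    dates: pd.DatetimeIndex
    X: np.ndarray
    day_of_week: np.ndarray  # 0=Monday .. 6=Sunday

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim == 2:
            self.X = self.X[:, :, None]
        if self.X.shape[1:] != (SLOTS_PER_DAY, 1):
            raise ValueError(f"X must be (n_days, {SLOTS_PER_DAY}, 1), got {self.X.shape}")
        if self.X.size and not np.isin(self.X, (0, 1)).all():
            raise ValueError("X entries must be binary")
        if not (len(self.dates) == self.X.shape[0] == len(self.day_of_week)):
            raise ValueError("dates, X and day_of_week must be aligned")
        if len(self.dates) > 1 and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")

    @property
    def n_days(self) -> int:
        return self.X.shape[0]

    @property
    def slots(self) -> np.ndarray:
        """(n_days, 48) view without the trailing channel axis."""
        return self.X[:, :, 0]

    def subset(self, idx) -> "DayMatrix":
        idx = np.asarray(idx)
        return DayMatrix(
            household_id=self.household_id,
            dates=self.dates[idx],
            X=self.X[idx],
            day_of_week=self.day_of_week[idx],
        )


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort filter: ≥8 sensors, ≥355 days online, ≤4 occupants by default."""

    min_sensors: int = 8
    min_days_online: int = 355
    max_occupants: int = 4

    def __post_init__(self) -> None:
        if min(self.min_sensors, self.min_days_online, self.max_occupants) < 1:
            raise ValueError("inclusion criteria must all be positive")


def motion_state(window_activations) -> int:
    """Binary motion state of one half-hour window (6 steps × k sensors).

    Returns 1 iff the total activation count is >= 4.
    """
    w = np.asarray(window_activations)
    if w.ndim == 1:
        w = w[:, None]
    if w.ndim != 2 or w.shape[0] != STEPS_PER_SLOT:
        raise ValueError(f"window must have exactly {STEPS_PER_SLOT} rows, got shape {w.shape}")
    if w.size and not np.isin(w, (0, 1)).all():
        raise ValueError("window entries must be binary")
    return int(w.sum() >= MOTION_SUM_THRESHOLD)


def build_day_matrix(panel: SensorPanel) -> DayMatrix:
    """Collapse a panel to one 48-slot binary row per complete calendar day.

    Days with fewer than 288 five-minute steps are dropped (and logged); a
    timestamp off the 5-minute grid is an error.
    """
    ts = panel.timestamps
    if len(ts) == 0:
        logger.warning("%s: empty panel, returning empty day matrix", panel.household_id)
        return DayMatrix(
            household_id=panel.household_id,
            dates=pd.DatetimeIndex([]),
            X=np.zeros((0, SLOTS_PER_DAY, 1), dtype=np.uint8),
            day_of_week=np.zeros(0, dtype=np.int64),
        )
    offsets = (ts - ts.normalize()).total_seconds().to_numpy()
    if np.any(offsets % 300 != 0):
        raise ValueError(f"{panel.household_id}: timestamps not aligned to the 5-minute grid")

    df = pd.DataFrame({"date": ts.normalize()})
    rows, dates = [], []
    for date, grp in df.groupby("date", sort=True):
        if len(grp) != STEPS_PER_DAY:
            logger.info(
                "%s: dropping incomplete day %s (%d/%d steps)",
                panel.household_id, date.date(), len(grp), STEPS_PER_DAY,
            )
            continue
        block = panel.activations[grp.index.to_numpy()]
        sums = block.reshape(SLOTS_PER_DAY, STEPS_PER_SLOT, -1).sum(axis=(1, 2))
        rows.append((sums >= MOTION_SUM_THRESHOLD).astype(np.uint8))
        dates.append(date)

    dates = pd.DatetimeIndex(dates)
    X = np.stack(rows)[:, :, None] if rows else np.zeros((0, SLOTS_PER_DAY, 1), dtype=np.uint8)
    return DayMatrix(
        household_id=panel.household_id,
        dates=dates,
        X=X,
        day_of_week=dates.dayofweek.to_numpy() if len(dates) else np.zeros(0, dtype=np.int64),
    )


def apply_inclusion(manifest: pd.DataFrame, criteria: InclusionCriteria) -> pd.DataFrame:
    """Filter a household manifest to the rows meeting every criterion.

    The occupant criterion applies only when the manifest carries an
    ``occupants`` column (real-world metadata may lack it).  Order preserved.
    """
    for col in ("n_sensors", "days_online"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
        bad = manifest[manifest[col].isna()]
        if len(bad):
            hh = bad.iloc[0].get("household_id", bad.index[0])
            raise ValueError(f"household {hh}: missing metadata field {col!r}")
    keep = (manifest["n_sensors"] >= criteria.min_sensors) & (
        manifest["days_online"] >= criteria.min_days_online
    )
    if "occupants" in manifest.columns:
        keep &= manifest["occupants"] <= criteria.max_occupants
    return manifest[keep].reset_index(drop=True)


def split_train_test(dm: DayMatrix, ratio: float = 0.8, seed: int = 0):
    """Random day-level partition into train/test; train size = round(ratio·n).

    Subsets keep chronological order internally; union of the two reconstructs
    the input exactly.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = dm.n_days
    if n < 2:
        raise ValueError("need at least 2 days to split")
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return dm.subset(train_idx), dm.subset(test_idx)


def write_day_matrix_csv(dm: DayMatrix, path) -> None:
    df = pd.DataFrame(dm.slots, columns=[f"slot_{i:02d}" for i in range(SLOTS_PER_DAY)])
    df.insert(0, "dow", dm.day_of_week)
    df.insert(0, "date", dm.dates.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False)


def read_day_matrix_csv(path, household_id: Optional[str] = None) -> DayMatrix:
    df = pd.read_csv(path)
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    slot_cols = [f"slot_{i:02d}" for i in range(SLOTS_PER_DAY)]
    return DayMatrix(
        household_id=household_id or "ingested",
        dates=dates,
        X=df[slot_cols].to_numpy(dtype=np.uint8),
        day_of_week=df["dow"].to_numpy(dtype=np.int64),
    )
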