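"""Behavioural indicators derived from the regular activity pattern.

The trained model's day-averaged reconstruction (posterior-mean latent, no
sampling noise) gives a household's *regular activity pattern*: 48 motion
probabilities, thresholded at 0.5 into a binary daily template.  From it we
read off public-health indicators:

* sleep time / wake-up time — endpoints of the longest circular run of
  motion-free slots (sleep typically spans midnight, hence circular);
* sleep duration — 30 minutes per slot in that run;
* minutes at home — 30 minutes per motion-positive slot, optionally also
  counting the sleep run as time at home;
* weekday-specific patterns — one model per day of the week;
* weekend vs weekday contrast — two-sided Mann–Whitney U test on per-day
  minutes at home.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import DayMatrix
from .simulate import SLOTS_PER_DAY, WEEKEND_DOWS
from .vae import LstmVae, VaeConfig, train

__all__ = [
    "RegularPattern",
    "BehaviorSummary",
    "regular_pattern",
    "extract_sleep_wake",
    "minutes_at_home",
    "weekday_models",
    "weekend_weekday_test",
    "summarize_behavior",
    "slot_to_hhmm",
    "write_behavior_csv",
]

logger = logging.getLogger(__name__)

MINUTES_PER_SLOT = 30

#: Tie-break anchor for the nightly sleep run: slot 6 = 03:00–03:30.
NIGHT_ANCHOR_SLOT = 6


@dataclass
class RegularPattern:
    """48-slot motion-probability template and its binarization."""

    probs: np.ndarray
    binary: np.ndarray
    source: str = "annual"  # annual | per_weekday

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.binary = np.asarray(self.binary, dtype=int)
        if self.probs.shape != (SLOTS_PER_DAY,) or self.binary.shape != (SLOTS_PER_DAY,):
            raise ValueError(f"pattern must have exactly {SLOTS_PER_DAY} slots")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probs must lie in [0, 1]")
        if not np.array_equal(self.binary, (self.probs >= 0.5).astype(int)):
            raise ValueError("binary must be probs thresholded at 0.5")


@dataclass
class BehaviorSummary:
    wake_slot: Optional[int]
    sleep_slot: Optional[int]
    sleep_duration_minutes: Optional[int]
    minutes_at_home_by_dow: np.ndarray  # 7 values, Monday..Sunday
    weekend_vs_weekday_stat: float
    weekend_vs_weekday_p: float
    at_home_mode: str = "motion"  # motion | motion_or_sleep


def regular_pattern(model: LstmVae, dm: DayMatrix, seed: int = 0) -> RegularPattern:
    """Day-averaged posterior-mean reconstruction, binarized at 0.5."""
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    if dm.n_days == 0:
        raise ValueError("day matrix is empty")
    probs = model.reconstruct(dm.slots.astype(float), mode="mean").mean(axis=0)
    return RegularPattern(probs=probs, binary=(probs >= 0.5).astype(int))


def _circular_zero_runs(binary: np.ndarray):
    """Maximal circular runs of zeros as (start, length) pairs."""
    n = len(binary)
    ones = np.flatnonzero(binary)
    if len(ones) == 0:
        return [(0, n)]
    runs = []
    for a, b in zip(ones, np.r_[ones[1:], ones[0] + n]):
        length = b - a - 1
        if length > 0:
            runs.append(((a + 1) % n, length))
    return runs


def extract_sleep_wake(rp) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """Sleep slot, wake slot and sleep duration from a binary pattern.

    The nightly sleep period is the longest circular run of motion-free slots.
    Ties prefer the run covering 03:00 (slot 6), else the earliest-starting
    run.  All-ones or all-zeros patterns have no identifiable sleep period and
    return (None, None, None).
    """
    binary = rp.binary if isinstance(rp, RegularPattern) else np.asarray(rp, dtype=int)
    n = len(binary)
    if binary.sum() in (0, n):
        return None, None, None
    runs = _circular_zero_runs(binary)
    best_len = max(length for _, length in runs)
    candidates = [(s, l) for s, l in runs if l == best_len]
    anchor = n // 8 if n != SLOTS_PER_DAY else NIGHT_ANCHOR_SLOT
    if len(candidates) > 1:
        anchored = [
            (s, l) for s, l in candidates if (anchor - s) % n < l
        ]
        if anchored:
            candidates = anchored
    start, length = min(candidates, key=lambda r: r[0])
    sleep_slot = start
    wake_slot = (start + length) % n
    return wake_slot, sleep_slot, length * MINUTES_PER_SLOT


def minutes_at_home(day_or_pattern, include_sleep: bool = False) -> int:
    """Minutes at home for one 48-slot binary vector.

    ``include_sleep=False`` counts motion-positive slots only (appropriate for
    raw single days).  ``include_sleep=True`` additionally counts the nightly
    sleep run of a regular-pattern binary as time at home (motion OR sleep).
    """
    vec = day_or_pattern.binary if isinstance(day_or_pattern, RegularPattern) else np.asarray(
        day_or_pattern, dtype=int
    )
    if vec.shape != (SLOTS_PER_DAY,):
        raise ValueError(f"expected a {SLOTS_PER_DAY}-slot binary vector, got {vec.shape}")
    minutes = int(vec.sum()) * MINUTES_PER_SLOT
    if include_sleep:
        _, _, dur = extract_sleep_wake(vec)
        if dur is not None:
            minutes += dur
    return min(minutes, 24 * 60)


def weekday_models(
    dm: DayMatrix,
    config: VaeConfig,
    seed: int = 0,
    min_days: int = 20,
    epochs: Optional[int] = None,
):
    """Train one model per day of the week; returns {dow: RegularPattern|None}.

    Each weekday subset gets its own model (seed offset by the weekday index);
    subsets smaller than ``min_days`` are skipped with a warning and map to
    None.
    """
    patterns: dict[int, Optional[RegularPattern]] = {}
    for dow in range(7):
        idx = np.flatnonzero(dm.day_of_week == dow)
        if len(idx) < min_days:
            logger.warning(
                "%s: only %d days for weekday %d (< %d); skipping",
                dm.household_id, len(idx), dow, min_days,
            )
            patterns[dow] = None
            continue
        sub = dm.subset(idx)
        cfg = replace(config, seed=(seed + dow) % 2**31,
                      epochs=config.epochs if epochs is None else epochs)
        model, _ = train(sub, cfg)
        rp = regular_pattern(model, sub)
        patterns[dow] = RegularPattern(rp.probs, rp.binary, source="per_weekday")
    return patterns


def weekend_weekday_test(minutes_per_day, day_of_week) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: weekend-day minutes vs weekday minutes."""
    minutes = np.asarray(minutes_per_day, dtype=float)
    dow = np.asarray(day_of_week)
    if minutes.shape != dow.shape:
        raise ValueError("minutes_per_day and day_of_week must be aligned")
    weekend = minutes[np.isin(dow, WEEKEND_DOWS)]
    weekday = minutes[~np.isin(dow, WEEKEND_DOWS)]
    if len(weekend) == 0 or len(weekday) == 0:
        raise ValueError("both weekend and weekday groups must be non-empty")
    if np.ptp(minutes) == 0:  # all tied: no evidence of any difference
        return float(len(weekend) * len(weekday) / 2.0), 1.0
    res = sps.mannwhitneyu(weekend, weekday, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def summarize_behavior(
    model: LstmVae, dm: DayMatrix, at_home_mode: str = "motion"
) -> BehaviorSummary:
    """Wake/sleep estimates plus day-of-week minutes at home and the contrast."""
    if at_home_mode not in ("motion", "motion_or_sleep"):
        raise ValueError(f"unknown at_home_mode {at_home_mode!r}")
    rp = regular_pattern(model, dm)
    wake, sleep, duration = extract_sleep_wake(rp)
    include_sleep = at_home_mode == "motion_or_sleep"
    per_day = np.array(
        [minutes_at_home(dm.slots[i], include_sleep=include_sleep) for i in range(dm.n_days)]
    )
    by_dow = np.array(
        [
            per_day[dm.day_of_week == d].mean() if np.any(dm.day_of_week == d) else np.nan
            for d in range(7)
        ]
    )
    stat, p = weekend_weekday_test(per_day, dm.day_of_week)
    return BehaviorSummary(
        wake_slot=wake,
        sleep_slot=sleep,
        sleep_duration_minutes=duration,
        minutes_at_home_by_dow=by_dow,
        weekend_vs_weekday_stat=stat,
        weekend_vs_weekday_p=p,
        at_home_mode=at_home_mode,
    )


def slot_to_hhmm(slot: Optional[int]) -> str:
    if slot is None:
        return ""
    return f"{slot // 2:02d}:{(slot % 2) * 30:02d}"


def write_behavior_csv(summary: BehaviorSummary, household_id: str, path) -> None:
    row = {
        "household_id": household_id,
        "wake_time": slot_to_hhmm(summary.wake_slot),
        "sleep_time": slot_to_hhmm(summary.sleep_slot),
        "sleep_duration_minutes": summary.sleep_duration_minutes,
        "at_home_mode": summary.at_home_mode,
        "weekend_vs_weekday_stat": round(summary.weekend_vs_weekday_stat, 6),
        "weekend_vs_weekday_p": round(summary.weekend_vs_weekday_p, 8),
    }
    for d, name in enumerate(["mon", "tue", "wed", "thu", "fri", "sat", "sun"]):
        v = summary.minutes_at_home_by_dow[d]
        row[f"minutes_at_home_{name}"] = None if np.isnan(v) else round(float(v), 2)
    pd.DataFrame([row]).to_csv(path, index=False)
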