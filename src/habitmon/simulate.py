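"""Synthetic household motion-sensor streams.

Emulates the data regime of consumer smart-thermostat deployments: a household
carries a handful of passive-infrared (PIR) sensors, each reporting a binary
activation flag every 5 minutes.  Occupants follow a daily schedule — wake,
(optionally) depart for the day, return, sleep — with an optional alternative
weekend schedule.  While the household is "active" every sensor fires
independently with probability ``p_fire_active`` per 5-minute step; while
asleep or away it fires spuriously with probability ``p_fire_idle``.

The generator injects labelled anomalous days (absence, insomnia, or a shifted
schedule) and can drop whole days to mimic connectivity outages, so the full
downstream pipeline — binarization, model training, anomaly flagging,
behavioural summaries — is exercisable without any proprietary corpus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleOverride",
    "HouseholdSpec",
    "SensorPanel",
    "generate_household",
    "generate_cohort",
    "write_panel_csv",
    "read_panel_csv",
    "write_cohort_manifest",
]

SLOTS_PER_DAY = 48
STEPS_PER_SLOT = 6
STEPS_PER_DAY = SLOTS_PER_DAY * STEPS_PER_SLOT  # 288 five-minute steps

#: Day-of-week anchoring: day index 0 of every panel is this date (a Monday),
#: so Saturdays/Sundays fall on day indices 5, 6, 12, 13, ...
DEFAULT_EPOCH = pd.Timestamp("2018-01-01")

WEEKEND_DOWS = (5, 6)  # Saturday, Sunday


@dataclass(frozen=True)
class ScheduleOverride:
    """Alternative wake/depart/return/sleep slots applied on weekend days."""

    wake_slot: int
    sleep_slot: int
    depart_slot: Optional[int] = None
    return_slot: Optional[int] = None


@dataclass(frozen=True)
class HouseholdSpec:
    """Parameters of one simulated household.

    Slot indices are half-hour slots of the day: slot 0 is 00:00–00:30, slot 11
    is 05:30–06:00, slot 47 is 23:30–00:00.  Defaults follow a working
    household that wakes at 05:30, leaves at 09:30, returns at 16:30 and goes
    to sleep at 22:30.
    """

    n_sensors: int = 8
    wake_slot: int = 11
    depart_slot: Optional[int] = 19
    return_slot: Optional[int] = 33
    sleep_slot: int = 45
    weekend_profile: Optional[ScheduleOverride] = None
    p_fire_active: float = 0.2
    p_fire_idle: float = 0.01
    n_days: int = 365
    missing_day_rate: float = 0.0
    anomaly_days: frozenset[int] = field(default_factory=frozenset)
    anomaly_mode: str = "absence"  # absence | insomnia | shifted
    shift_slots: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "anomaly_days", frozenset(self.anomaly_days))
        self.validate()

    def validate(self) -> None:
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be a positive integer")
        if self.n_days < 1:
            raise ValueError("n_days must be a positive integer")
        for name in ("wake_slot", "sleep_slot"):
            v = getattr(self, name)
            if not 0 <= v < SLOTS_PER_DAY:
                raise ValueError(f"{name}={v} outside slot range 0..{SLOTS_PER_DAY - 1}")
        if not self.wake_slot < self.sleep_slot:
            raise ValueError("invariant violated: wake_slot < sleep_slot")
        if (self.depart_slot is None) != (self.return_slot is None):
            raise ValueError("depart_slot and return_slot must be given together")
        if self.depart_slot is not None:
            if not (self.wake_slot < self.depart_slot < self.return_slot):
                raise ValueError(
                    "invariant violated: depart_slot must lie in (wake_slot, return_slot)"
                )
            if not self.return_slot < self.sleep_slot:
                raise ValueError("invariant violated: return_slot < sleep_slot")
        if not 0.0 <= self.p_fire_idle <= 1.0 or not 0.0 <= self.p_fire_active <= 1.0:
            raise ValueError("firing probabilities must lie in [0, 1]")
        if not self.p_fire_active > self.p_fire_idle:
            raise ValueError(
                "invariant violated: p_fire_active must exceed p_fire_idle "
                "(otherwise the schedule carries no signal)"
            )
        if not 0.0 <= self.missing_day_rate <= 1.0:
            raise ValueError("missing_day_rate must lie in [0, 1]")
        bad = [d for d in self.anomaly_days if not 0 <= d < self.n_days]
        if bad:
            raise ValueError(
                f"invariant violated: anomaly_days {sorted(bad)} outside 0..{self.n_days - 1}"
            )
        if self.anomaly_mode not in ("absence", "insomnia", "shifted"):
            raise ValueError(f"unknown anomaly_mode {self.anomaly_mode!r}")

    def replace(self, **kwargs) -> "HouseholdSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SensorPanel:
    """One household-year of per-sensor 5-minute binary activations.

    ``timestamps`` is a strictly increasing 5-minute grid; whole days may be
    absent (connectivity gaps) but never partial days.  ``anomaly_labels``
    holds the synthetic ground truth, one 0/1 entry per present calendar day.
    """

    household_id: str
    timestamps: pd.DatetimeIndex
    activations: np.ndarray  # (n_steps, n_sensors) of {0,1}
    anomaly_labels: np.ndarray  # (n_present_days,) of {0,1}
    days_online: int

    @property
    def n_sensors(self) -> int:
        return self.activations.shape[1]

    @property
    def dates(self) -> list:
        return sorted(set(self.timestamps.date))

    def __post_init__(self) -> None:
        if len(self.timestamps) != self.activations.shape[0]:
            raise ValueError("timestamps and activations length mismatch")
        if self.activations.size and not np.isin(self.activations, (0, 1)).all():
            raise ValueError("activations must be binary")
        n_days = len(set(self.timestamps.date))
        if len(self.anomaly_labels) != n_days:
            raise ValueError("anomaly_labels must have one entry per present day")


def _active_slot_mask(
    wake: int, sleep: int, depart: Optional[int], ret: Optional[int]
) -> np.ndarray:
    mask = np.zeros(SLOTS_PER_DAY, dtype=bool)
    if depart is None:
        mask[wake:sleep] = True
    else:
        mask[wake:depart] = True
        mask[ret:sleep] = True
    return mask


def _day_active_mask(spec: HouseholdSpec, dow: int, anomalous: bool) -> np.ndarray:
    """Half-hour occupancy-state mask for one day (True = occupants active)."""
    prof = spec.weekend_profile
    if dow in WEEKEND_DOWS and prof is not None:
        mask = _active_slot_mask(
            prof.wake_slot, prof.sleep_slot, prof.depart_slot, prof.return_slot
        )
    else:
        mask = _active_slot_mask(
            spec.wake_slot, spec.sleep_slot, spec.depart_slot, spec.return_slot
        )
    if not anomalous:
        return mask
    if spec.anomaly_mode == "absence":
        return np.zeros_like(mask)
    if spec.anomaly_mode == "insomnia":
        out = mask.copy()
        out[: spec.wake_slot] = True
        out[spec.sleep_slot :] = True
        return out
    # shifted: whole schedule rotated forward by shift_slots
    return np.roll(mask, spec.shift_slots)


def generate_household(spec: HouseholdSpec, household_id: str = "HH000") -> SensorPanel:
    """Simulate one household's sensor stream; identical spec+seed ⇒ identical panel."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # choose whole missing days (never an injected anomaly day, so every label survives)
    missing = np.zeros(spec.n_days, dtype=bool)
    if spec.missing_day_rate > 0:
        missing = rng.random(spec.n_days) < spec.missing_day_rate
        for d in spec.anomaly_days:
            missing[d] = False

    day_blocks = []
    label_list = []
    kept_days = []
    for d in range(spec.n_days):
        is_anom = d in spec.anomaly_days
        dow = (DEFAULT_EPOCH + pd.Timedelta(days=d)).dayofweek
        slot_mask = _day_active_mask(spec, dow, is_anom)
        p_step = np.where(
            np.repeat(slot_mask, STEPS_PER_SLOT), spec.p_fire_active, spec.p_fire_idle
        )
        # draw even for missing days so the stream of randomness is stable
        draws = rng.random((STEPS_PER_DAY, spec.n_sensors))
        if missing[d]:
            continue
        day_blocks.append((draws < p_step[:, None]).astype(np.uint8))
        label_list.append(1 if is_anom else 0)
        kept_days.append(d)

    if day_blocks:
        activations = np.concatenate(day_blocks, axis=0)
        ts = pd.DatetimeIndex(
            np.concatenate(
                [
                    (DEFAULT_EPOCH + pd.Timedelta(days=d)).value
                    + np.arange(STEPS_PER_DAY) * pd.Timedelta(minutes=5).value
                    for d in kept_days
                ]
            ).astype("datetime64[ns]")
        )
    else:  # pragma: no cover - pathological missing_day_rate=1 draws
        activations = np.zeros((0, spec.n_sensors), dtype=np.uint8)
        ts = pd.DatetimeIndex([], dtype="datetime64[ns]")

    return SensorPanel(
        household_id=household_id,
        timestamps=ts,
        activations=activations,
        anomaly_labels=np.asarray(label_list, dtype=np.uint8),
        days_online=len(kept_days),
    )


def generate_cohort(
    n_households: int,
    base_spec: HouseholdSpec,
    seed: int,
    jitter_slots: int = 2,
) -> list[SensorPanel]:
    """Simulate ``n_households`` with per-household schedule jitter.

    Each household's four schedule slots are shifted by one offset drawn
    uniformly from ``[-jitter_slots, +jitter_slots]`` (a shared offset keeps
    the wake < depart < return < sleep ordering intact), and receives its own
    child seed, so the call is reproducible bit-for-bit under ``seed``.
    """
    if n_households < 1:
        raise ValueError("n_households must be >= 1")
    rng = np.random.default_rng(seed)
    # keep every jittered slot inside 0..47
    slots = [base_spec.wake_slot, base_spec.sleep_slot]
    if base_spec.depart_slot is not None:
        slots += [base_spec.depart_slot, base_spec.return_slot]
    if base_spec.weekend_profile is not None:
        prof0 = base_spec.weekend_profile
        slots += [s for s in (prof0.wake_slot, prof0.sleep_slot,
                              prof0.depart_slot, prof0.return_slot) if s is not None]
    lo, hi = -min(slots), SLOTS_PER_DAY - 1 - max(slots)
    panels = []
    for i in range(n_households):
        offset = 0
        if jitter_slots:
            offset = int(rng.integers(-jitter_slots, jitter_slots + 1))
            offset = int(np.clip(offset, lo, hi))
        child_seed = int(rng.integers(0, 2**31))
        prof = base_spec.weekend_profile
        if prof is not None:
            prof = ScheduleOverride(
                wake_slot=prof.wake_slot + offset,
                sleep_slot=prof.sleep_slot + offset,
                depart_slot=None if prof.depart_slot is None else prof.depart_slot + offset,
                return_slot=None if prof.return_slot is None else prof.return_slot + offset,
            )
        spec = base_spec.replace(
            wake_slot=base_spec.wake_slot + offset,
            sleep_slot=base_spec.sleep_slot + offset,
            depart_slot=None if base_spec.depart_slot is None else base_spec.depart_slot + offset,
            return_slot=None if base_spec.return_slot is None else base_spec.return_slot + offset,
            weekend_profile=prof,
            seed=child_seed,
        )
        panels.append(generate_household(spec, household_id=f"HH{i:03d}"))
    return panels


# ---------------------------------------------------------------------------
# CSV dialect: `timestamp, sensor_0, ..., sensor_{k-1}` plus a day-label sidecar


def write_panel_csv(panel: SensorPanel, path, labels_path=None) -> None:
    df = pd.DataFrame(
        panel.activations,
        columns=[f"sensor_{j}" for j in range(panel.n_sensors)],
    )
    df.insert(0, "timestamp", panel.timestamps.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)
    if labels_path is not None:
        dates = pd.DatetimeIndex(sorted(set(panel.timestamps.normalize())))
        pd.DataFrame(
            {"date": dates.strftime("%Y-%m-%d"), "is_anomaly": panel.anomaly_labels}
        ).to_csv(labels_path, index=False)


def read_panel_csv(path, household_id: Optional[str] = None, labels_path=None) -> SensorPanel:
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    sensor_cols = [c for c in df.columns if c.startswith("sensor_")]
    act = df[sensor_cols].to_numpy()
    act = np.nan_to_num(act, nan=0.0).astype(np.uint8)  # absent report ≈ no motion
    n_days = len(set(ts.date))
    if labels_path is not None:
        labels = pd.read_csv(labels_path)["is_anomaly"].to_numpy(dtype=np.uint8)
    else:
        labels = np.zeros(n_days, dtype=np.uint8)
    return SensorPanel(
        household_id=household_id or Path(path).stem,
        timestamps=ts,
        activations=act,
        anomaly_labels=labels,
        days_online=n_days,
    )


def write_cohort_manifest(panels: Sequence[SensorPanel], path) -> pd.DataFrame:
    manifest = pd.DataFrame(
        {
            "household_id": [p.household_id for p in panels],
            "n_sensors": [p.n_sensors for p in panels],
            "days_online": [p.days_online for p in panels],
        }
    )
    manifest.to_csv(path, index=False)
    return manifest
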