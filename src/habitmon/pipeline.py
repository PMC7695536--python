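"""End-to-end orchestration: simulate or ingest → preprocess → train → detect → summarize.

One model is trained per household.  All stages are driven by a single
:class:`PipelineConfig` (loadable from a YAML file whose defaults reproduce
the reference configuration), seeded once, and write deterministic CSV
outputs, so re-running an identical config reproduces every file byte for
byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import anomaly as anomaly_mod
from . import behavior as behavior_mod
from .preprocess import (
    InclusionCriteria,
    apply_inclusion,
    build_day_matrix,
    split_train_test,
    write_day_matrix_csv,
)
from .simulate import (
    HouseholdSpec,
    generate_cohort,
    read_panel_csv,
    write_cohort_manifest,
    write_panel_csv,
)
from .vae import VaeConfig, save_model, train

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run"]


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # simulate | ingest
    n_households: int = 3
    household: HouseholdSpec = field(default_factory=HouseholdSpec)
    input_paths: list = field(default_factory=list)  # panel CSVs (ingest mode)
    validation_paths: list = field(default_factory=list)  # optional second-year panels
    criteria: InclusionCriteria = field(default_factory=InclusionCriteria)
    vae: VaeConfig = field(default_factory=VaeConfig)
    split_ratio: float = 0.8
    outdir: str = "habitmon_out"
    seed: int = 0
    jitter_slots: int = 2
    at_home_mode: str = "motion"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "household" in kwargs:
            kwargs["household"] = HouseholdSpec(**kwargs["household"])
        if "criteria" in kwargs:
            kwargs["criteria"] = InclusionCriteria(**kwargs["criteria"])
        if "vae" in kwargs:
            kwargs["vae"] = VaeConfig(**kwargs["vae"])
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violated invariant; an empty list means the config is ok."""
    violations = []
    if config.mode not in ("simulate", "ingest"):
        violations.append(f"mode must be 'simulate' or 'ingest', got {config.mode!r}")
    if not 0.0 < config.split_ratio < 1.0:
        violations.append(f"split_ratio must lie strictly in (0, 1), got {config.split_ratio}")
    if config.mode == "simulate" and config.n_households < 1:
        violations.append("n_households must be >= 1 in simulate mode")
    if config.mode == "ingest":
        if not config.input_paths:
            violations.append("ingest mode requires at least one input path")
        for p in [*config.input_paths, *config.validation_paths]:
            if not Path(p).exists():
                violations.append(f"input path does not exist: {p}")
    if config.at_home_mode not in ("motion", "motion_or_sleep"):
        violations.append(f"unknown at_home_mode {config.at_home_mode!r}")
    try:
        config.household.validate()
    except ValueError as e:
        violations.append(f"household spec: {e}")
    return violations


def _load_panels(config: PipelineConfig):
    if config.mode == "simulate":
        return generate_cohort(
            config.n_households, config.household, seed=config.seed,
            jitter_slots=config.jitter_slots,
        )
    panels = []
    for p in config.input_paths:
        path = Path(p)
        # panels exported by this pipeline live at <household_id>/panel.csv
        hid = path.parent.name if path.stem == "panel" else path.stem
        panels.append(read_panel_csv(p, household_id=hid))
    return panels


def run(config: PipelineConfig) -> dict:
    """Execute the full flow; returns {household_id: output-row dict}.

    Per household: day-matrix CSV, loss-history CSV, per-day anomaly CSV,
    behaviour summary CSV and a model checkpoint; a cohort CSV aggregates the
    Table-1-style rows.  A MANIFEST file records which stages completed.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_lines = []

    panels = _load_panels(config)
    manifest = write_cohort_manifest(panels, outdir / "cohort_manifest.csv")
    kept = apply_inclusion(manifest, config.criteria)
    kept_ids = set(kept["household_id"])
    logger.info("inclusion criteria kept %d/%d households", len(kept_ids), len(panels))

    validation_panels = {}
    for p in config.validation_paths:
        panel = read_panel_csv(p)
        validation_panels[panel.household_id] = panel

    reports, results = [], {}
    for panel in panels:
        if panel.household_id not in kept_ids:
            manifest_lines.append(f"{panel.household_id}: excluded (inclusion criteria)")
            continue
        hid = panel.household_id
        hdir = outdir / hid
        hdir.mkdir(exist_ok=True)
        try:
            t0 = time.perf_counter()
            if config.mode == "simulate":
                write_panel_csv(panel, hdir / "panel.csv", hdir / "panel_labels.csv")
            dm = build_day_matrix(panel)
            write_day_matrix_csv(dm, hdir / "day_matrix.csv")
            train_dm, test_dm = split_train_test(dm, config.split_ratio, seed=config.seed)
            logger.info("%s: %d days (%d train / %d test)",
                        hid, dm.n_days, train_dm.n_days, test_dm.n_days)

            model, history = train(train_dm, replace(config.vae, seed=config.seed))
            history.to_csv(hdir / "loss_history.csv", index=False, float_format="%.8f")
            save_model(model, hdir / "model.npz")

            # score the held-out year if provided, else the full observed year
            if hid in validation_panels:
                score_dm = build_day_matrix(validation_panels[hid])
            else:
                score_dm = dm
            scores = anomaly_mod.score_days(model, score_dm, seed=config.seed)
            auc = anomaly_mod.validation_auc(model, score_dm, seed=config.seed)
            report = anomaly_mod.summarize_household(
                hid, score_dm.dates, scores, score_dm.day_of_week, auc=auc
            )
            anomaly_mod.write_daily_csv(report, hdir / "anomaly_days.csv")
            reports.append(report)

            summary = behavior_mod.summarize_behavior(model, dm, at_home_mode=config.at_home_mode)
            behavior_mod.write_behavior_csv(summary, hid, hdir / "behavior_summary.csv")

            results[hid] = {
                "report": report,
                "behavior": summary,
                "n_days": dm.n_days,
            }
            manifest_lines.append(f"{hid}: complete ({time.perf_counter() - t0:.1f}s)")
        except Exception as e:
            manifest_lines.append(f"{hid}: FAILED ({e})")
            (outdir / "MANIFEST").write_text("\n".join(manifest_lines) + "\n")
            raise RuntimeError(f"pipeline failed for household {hid}: {e}") from e

    anomaly_mod.write_report_csv(reports, outdir / "cohort_report.csv")
    manifest_lines.append("cohort_report: complete")
    (outdir / "MANIFEST").write_text("\n".join(manifest_lines) + "\n")
    return results
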