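"""End-to-end orchestration: cohort -> exclusions -> derivation -> reports.

``run_pipeline`` executes the full analysis on a cohort read from CSV or
simulated on the fly, and writes five report files plus the exclusion log
and a run log:

* ``vitals_summary.csv``   — n, median and IQR per predictor
* ``roc_auc.csv``          — AUC, CI and DeLong comparison vs the reference
* ``roc_curves.csv``       — empirical ROC curve points per predictor/outcome
* ``thresholds.csv``       — operating characteristics at each cut-point
* ``centiles.csv``         — predictor values at target specificity levels

Reports are plain CSV with machine-readable significance columns; every
percentage can be re-derived from the count columns emitted next to it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centiles as centiles_mod
from . import roc as roc_mod
from . import thresholds as thresholds_mod
from .cohort import Cohort, apply_exclusions, read_cohort, write_cohort
from .derive import SELECTION_RULES, derive_table
from .outcomes import OUTCOMES, attach_outcomes
from .simulate import GeneratorParams, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration references unknown predictors/outcomes/rules."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    input_path: str | None = None
    n: int = 958
    seed: int = 42
    window_minutes: int = 60
    selection_rule: str = "max_si"
    predictors: tuple = tuple(roc_mod.PREDICTORS)
    outcomes: tuple = tuple(OUTCOMES)
    reference: str = "si"
    bonferroni_m: int | None = None
    thresholds: tuple = (0.7, 0.9, 1.4, 1.7)
    centile_levels: tuple = tuple(centiles_mod.DEFAULT_LEVELS)
    output_dir: str = "vsalert_reports"
    write_cohort_csv: bool = True
    generator_params: GeneratorParams | None = None

    def validate(self) -> None:
        unknown = [p for p in self.predictors if p not in roc_mod.PREDICTORS]
        if unknown:
            raise ConfigError(f"unknown predictors: {unknown}")
        unknown = [o for o in self.outcomes if o not in OUTCOMES]
        if unknown:
            raise ConfigError(f"unknown outcomes: {unknown}")
        if self.reference not in self.predictors:
            raise ConfigError(
                f"reference {self.reference!r} not among predictors"
            )
        if self.selection_rule not in SELECTION_RULES:
            raise ConfigError(f"unknown selection rule {self.selection_rule!r}")
        if self.window_minutes <= 0:
            raise ConfigError("window_minutes must be positive")


def _load_or_simulate(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    params = config.generator_params
    if params is None:
        params = GeneratorParams(n=config.n, seed=config.seed)
    return generate_cohort(params)


def vitals_summary(derived: pd.DataFrame, predictors) -> pd.DataFrame:
    """Median / IQR summary of the derived predictors (Table-2 analogue)."""
    rows = []
    for predictor in predictors:
        values = derived[predictor].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        rows.append(
            {
                "predictor": predictor,
                "n": int(len(values)),
                "median": float(np.median(values)) if len(values) else np.nan,
                "q1": float(np.quantile(values, 0.25)) if len(values) else np.nan,
                "q3": float(np.quantile(values, 0.75)) if len(values) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def build_analysis_table(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    """Excluded, derived and outcome-annotated per-patient table."""
    retained, _ = apply_exclusions(cohort, config.window_minutes)
    derived = derive_table(retained, config.window_minutes, config.selection_rule)
    return attach_outcomes(derived, retained)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all reports.

    Returns the report bundle as a dict of DataFrames (plus the exclusion
    log and run log dict).  On a stage failure, files already written for
    this run are removed and :class:`StageError` is raised.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    run_log: dict = {"config": {k: list(v) if isinstance(v, tuple) else v
                                for k, v in asdict(config).items()},
                     "stages": {}}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    stage = "setup"
    try:
        stage = "load"
        cohort = _load_or_simulate(config)
        run_log["stages"]["load"] = {"n": len(cohort),
                                     "provenance": cohort.provenance}
        if config.write_cohort_csv and config.input_path is None:
            path = out_dir / "cohort.csv"
            write_cohort(cohort, path)
            written.append(path)

        stage = "exclusions"
        retained, exclusion_log = apply_exclusions(cohort, config.window_minutes)
        path = out_dir / "exclusions.jsonl"
        path.write_text("".join(json.dumps(e) + "\n" for e in exclusion_log))
        written.append(path)
        run_log["stages"]["exclusions"] = {
            "input": len(cohort),
            "retained": len(retained),
            "excluded": len(exclusion_log),
        }

        stage = "derive"
        derived = derive_table(
            retained, config.window_minutes, config.selection_rule
        )
        table = attach_outcomes(derived, retained)
        emit("derived.csv", table)
        run_log["stages"]["derive"] = {
            "rule": config.selection_rule,
            "n": int(len(table)),
            "n_with_si": int(table["si"].notna().sum()),
        }

        stage = "vitals_summary"
        summary = vitals_summary(table, config.predictors)
        emit("vitals_summary.csv", summary)

        stage = "roc"
        auc_table = roc_mod.roc_table(
            table,
            predictors=config.predictors,
            outcomes=config.outcomes,
            reference=config.reference,
            bonferroni_m=config.bonferroni_m,
        )
        emit("roc_auc.csv", auc_table)
        curves = []
        for outcome in config.outcomes:
            y = table[outcome].astype(bool).to_numpy()
            for predictor in config.predictors:
                s = table[predictor].to_numpy(dtype=float)
                keep = ~np.isnan(s)
                curve = roc_mod.roc_curve_points(
                    s[keep], y[keep],
                    roc_mod.ORIENTATION.get(predictor, "higher_is_worse"),
                )
                curve.insert(0, "predictor", predictor)
                curve.insert(1, "outcome", outcome)
                curves.append(curve)
        emit("roc_curves.csv", pd.concat(curves, ignore_index=True))
        run_log["stages"]["roc"] = {
            "cells": int(len(auc_table)),
            "n_by_predictor": {
                p: int(table[p].notna().sum()) for p in config.predictors
            },
        }

        stage = "thresholds"
        thr = thresholds_mod.threshold_table(
            table,
            predictor=config.reference,
            thresholds=config.thresholds,
            outcomes=config.outcomes,
        )
        emit("thresholds.csv", thr)

        stage = "centiles"
        cent = centiles_mod.centile_table(
            table,
            predictor=config.reference,
            outcomes=config.outcomes,
            levels=config.centile_levels,
        )
        emit("centiles.csv", cent)

        stage = "run_log"
        (out_dir / "run_log.json").write_text(
            json.dumps(run_log, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:  # remove partial outputs, re-raise stage-tagged
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, ConfigError):
            raise
        raise StageError(stage, exc) from exc

    return {
        "derived": table,
        "vitals_summary": summary,
        "roc_auc": auc_table,
        "thresholds": thr,
        "centiles": cent,
        "exclusions": exclusion_log,
        "run_log": run_log,
    }


def worst_point_sensitivity_report(
    config: RunConfig, spread_flag: float = 0.05
) -> pd.DataFrame:
    """AUC per predictor x outcome under each of the four selection rules.

    The ``spread`` column is max - min AUC across rules for the cell;
    ``spread_exceeds`` flags cells where it exceeds ``spread_flag``.
    """
    config.validate()
    cohort = _load_or_simulate(config)
    retained, _ = apply_exclusions(cohort, config.window_minutes)
    pieces = []
    for rule in SELECTION_RULES:
        derived = derive_table(retained, config.window_minutes, rule)
        table = attach_outcomes(derived, retained)
        auc = roc_mod.roc_table(
            table,
            predictors=config.predictors,
            outcomes=config.outcomes,
            reference=None,
        )
        auc.insert(0, "selection_rule", rule)
        pieces.append(auc[["selection_rule", "predictor", "outcome", "n", "auc"]])
    long = pd.concat(pieces, ignore_index=True)
    wide = long.pivot_table(
        index=["predictor", "outcome"], columns="selection_rule", values="auc"
    ).reset_index()
    rule_cols = [r for r in SELECTION_RULES if r in wide.columns]
    wide["spread"] = wide[rule_cols].max(axis=1) - wide[rule_cols].min(axis=1)
    wide["spread_exceeds"] = wide["spread"] > spread_flag
    wide.columns.name = None
    return wide
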