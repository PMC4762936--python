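"""Derived hemodynamic indices and worst-point selection.

Indices
-------
shock index (SI)
    pulse / SBP, dimensionless.  Values around 0.5-0.7 are normal in
    non-pregnant adults; higher values indicate hemodynamic compromise.
mean arterial pressure (MAP)
    (2*DBP + SBP) / 3 mmHg; MAP below 60 mmHg is taken as severe shock
    (inadequate perfusion of vital organs).
pulse pressure
    SBP - DBP, mmHg.

The analysis point for each patient is the observation in the first hour
with the highest SI ("worst point").  Three alternative selection rules —
highest pulse, lowest SBP, lowest MAP — support a sensitivity analysis of
that choice.  All indices are computed at the single selected time point;
ties on the selection statistic are broken toward the earliest time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, PatientRecord, VitalObservation

SELECTION_RULES = ("max_si", "max_pulse", "min_sbp", "min_map")

#: MAP below this value (mmHg, strict) defines severe shock.
SEVERE_SHOCK_MAP_MMHG = 60.0


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def shock_index(pulse: float | None, sbp: float | None) -> float:
    """Pulse divided by systolic blood pressure (unrounded).

    Missing or non-positive inputs give NaN rather than raising, so the
    function can run over raw observation series.
    """
    if _missing(pulse) or _missing(sbp) or sbp <= 0 or pulse <= 0:
        return math.nan
    return pulse / sbp


def mean_arterial_pressure(sbp: float | None, dbp: float | None) -> float:
    """(2*DBP + SBP) / 3; NaN when either pressure is missing."""
    if _missing(sbp) or _missing(dbp):
        return math.nan
    return (2.0 * dbp + sbp) / 3.0


def pulse_pressure(sbp: float | None, dbp: float | None) -> float:
    """SBP - DBP; NaN when either pressure is missing."""
    if _missing(sbp) or _missing(dbp):
        return math.nan
    return sbp - dbp


def severe_shock_flag(map_mmhg: float | None) -> bool | None:
    """True iff MAP < 60 mmHg (strict); None when MAP is missing."""
    if _missing(map_mmhg):
        return None
    return map_mmhg < SEVERE_SHOCK_MAP_MMHG


@dataclass
class DerivedPoint:
    """The selected worst-point vitals with all derivable indices."""

    patient_id: str
    minutes_from_entry: int
    pulse: float
    sbp: float
    dbp: float
    si: float
    map: float
    pulse_pressure: float
    severe_shock: bool | None
    selection_rule: str


def _rule_statistic(obs: VitalObservation, rule: str) -> float:
    """The (signed) statistic the rule maximizes; NaN when not computable."""
    if rule == "max_si":
        return shock_index(obs.pulse, obs.sbp)
    if rule == "max_pulse":
        return math.nan if _missing(obs.pulse) else obs.pulse
    if rule == "min_sbp":
        return math.nan if _missing(obs.sbp) else -obs.sbp
    if rule == "min_map":
        m = mean_arterial_pressure(obs.sbp, obs.dbp)
        return -m if not math.isnan(m) else math.nan
    raise ValueError(f"unknown selection rule {rule!r}")


def select_worst_point(
    record: PatientRecord,
    window_minutes: int = 60,
    rule: str = "max_si",
) -> DerivedPoint | None:
    """Select the extremal observation in [0, window_minutes] under ``rule``.

    Observations missing the fields the rule needs are skipped.  Returns
    ``None`` when no observation in the window can be scored, in which
    case the record drops out of analyses using that rule.  Ties are
    broken toward the earliest observation (strict-improvement scan in
    time order).
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"unknown selection rule {rule!r}")
    best: VitalObservation | None = None
    best_stat = -math.inf
    for obs in record.observations_within(window_minutes):
        stat = _rule_statistic(obs, rule)
        if math.isnan(stat):
            continue
        if stat > best_stat:
            best, best_stat = obs, stat
    if best is None:
        return None
    si = shock_index(best.pulse, best.sbp)
    map_mmhg = mean_arterial_pressure(best.sbp, best.dbp)
    return DerivedPoint(
        patient_id=record.patient_id,
        minutes_from_entry=best.minutes_from_entry,
        pulse=math.nan if _missing(best.pulse) else best.pulse,
        sbp=math.nan if _missing(best.sbp) else best.sbp,
        dbp=math.nan if _missing(best.dbp) else best.dbp,
        si=si,
        map=map_mmhg,
        pulse_pressure=pulse_pressure(best.sbp, best.dbp),
        severe_shock=severe_shock_flag(map_mmhg),
        selection_rule=rule,
    )


def derive_table(
    cohort: Cohort,
    window_minutes: int = 60,
    rule: str = "max_si",
) -> pd.DataFrame:
    """One row per patient with the selected point and derived indices.

    Patients with no scoreable observation under the rule appear with
    missing derived fields so downstream joins keep the full cohort; each
    analysis then drops missing predictor values on its own denominator.
    """
    rows = []
    for record in cohort:
        point = select_worst_point(record, window_minutes, rule)
        if point is None:
            rows.append(
                {
                    "patient_id": record.patient_id,
                    "selection_rule": rule,
                    "minutes_from_entry": math.nan,
                    "pulse": math.nan,
                    "sbp": math.nan,
                    "dbp": math.nan,
                    "si": math.nan,
                    "map": math.nan,
                    "pulse_pressure": math.nan,
                    "severe_shock": None,
                }
            )
        else:
            rows.append(
                {
                    "patient_id": point.patient_id,
                    "selection_rule": rule,
                    "minutes_from_entry": point.minutes_from_entry,
                    "pulse": point.pulse,
                    "sbp": point.sbp,
                    "dbp": point.dbp,
                    "si": point.si,
                    "map": point.map,
                    "pulse_pressure": point.pulse_pressure,
                    "severe_shock": point.severe_shock,
                }
            )
    return pd.DataFrame(rows)
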