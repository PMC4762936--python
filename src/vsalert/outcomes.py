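"""Analysis outcomes built from raw outcome fields.

Three nested composites, following the WHO maternal near-miss framework:

death
    maternal death.
SMO (severe maternal outcome)
    death OR severe end-organ failure morbidity.
SMO-CI (SMO or critical intervention)
    SMO OR ICU admission OR blood transfusion of >= 5 units OR emergency
    hysterectomy for a uterine-atony diagnosis.

Nesting (death implies SMO implies SMO-CI) holds by construction.  Missing
component fields are treated as false with a logged warning, so every
record with a known death status contributes to every composite rather
than being dropped case-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, PatientRecord

logger = logging.getLogger(__name__)

OUTCOMES = ("death", "smo", "smo_ci")

#: Transfusion volume (units) at or above which the critical-intervention
#: criterion is met (inclusive threshold).
TRANSFUSION_UNITS_THRESHOLD = 5


@dataclass(frozen=True)
class OutcomeFlags:
    death: bool
    smo: bool
    smo_ci: bool

    def __post_init__(self) -> None:
        if self.death and not self.smo or self.smo and not self.smo_ci:
            raise ValueError("outcome flags must be nested: death => smo => smo_ci")


def build_outcomes(record: PatientRecord) -> OutcomeFlags:
    """Construct (death, SMO, SMO-CI) flags for one record.

    Raises ``ValueError`` when the death status is missing: such records
    must already have been removed by the exclusion step.
    """
    if record.died is None:
        raise ValueError(
            f"patient {record.patient_id}: death status missing; "
            "apply_exclusions must run before outcome construction"
        )

    def as_bool(value, name: str) -> bool:
        if value is None:
            logger.warning(
                "patient %s: missing %s treated as false", record.patient_id, name
            )
            return False
        return bool(value)

    death = bool(record.died)
    smo = death or as_bool(record.end_organ_failure, "end_organ_failure")
    hysterectomy_ci = (
        as_bool(record.emergency_hysterectomy, "emergency_hysterectomy")
        and record.diagnosis == "uterine_atony"
    )
    units = record.transfusion_units
    if units is None:
        logger.warning(
            "patient %s: missing transfusion_units treated as 0", record.patient_id
        )
        units = 0
    smo_ci = (
        smo
        or as_bool(record.icu_admission, "icu_admission")
        or units >= TRANSFUSION_UNITS_THRESHOLD
        or hysterectomy_ci
    )
    return OutcomeFlags(death=death, smo=smo, smo_ci=smo_ci)


def outcome_table(cohort: Cohort) -> pd.DataFrame:
    """One row per patient with boolean death / smo / smo_ci columns."""
    rows = []
    for record in cohort:
        flags = build_outcomes(record)
        rows.append(
            {
                "patient_id": record.patient_id,
                "death": flags.death,
                "smo": flags.smo,
                "smo_ci": flags.smo_ci,
            }
        )
    return pd.DataFrame(rows)


def attach_outcomes(derived: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Append outcome columns to a derived-vitals table by patient_id."""
    return derived.merge(outcome_table(cohort), on="patient_id", how="left")
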