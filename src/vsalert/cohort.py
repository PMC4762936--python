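"""Cohort tables: schema, validation, eligibility and exclusion rules.

The analysis operates on patient-level records of timed vital-sign
observations (pulse, systolic and diastolic blood pressure, nominally on a
15-minute grid during the first hour after study entry) together with a
hemorrhage diagnosis, estimated blood loss at entry, and raw outcome
fields (death, end-organ failure, ICU admission, units transfused,
emergency hysterectomy).

Cohorts are exchanged as long-format CSV: one row per observation, with
patient-level fields repeated on every row.  Vital-sign cells may contain
the literal token ``NP`` (non-palpable), which parses to a missing value
carrying a flag; records whose only vital-sign information is non-palpable
are removed by :func:`apply_exclusions`, mirroring the study's handling of
patients too unstable for any measurable reading.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Hemorrhage etiologies accepted in the ``diagnosis`` column.
DIAGNOSES = (
    "uterine_atony",
    "abortion_complications",
    "retained_placenta",
    "ectopic",
    "abruption",
    "ruptured_uterus",
    "previa",
    "lacerations",
    "molar",
    "accreta",
    "other",
    "missing",
)

ENTRY_CONTEXTS = ("phc", "tertiary")

#: Default estimated-blood-loss entry thresholds (mL) by entry context:
#: primary health clinic enrollment used >500 mL, tertiary >750 mL.
EBL_THRESHOLDS_ML = {"phc": 500.0, "tertiary": 750.0}

COLUMNS = [
    "patient_id",
    "entry_context",
    "ebl_ml",
    "diagnosis",
    "minutes_from_entry",
    "pulse",
    "sbp",
    "dbp",
    "died",
    "end_organ_failure",
    "icu_admission",
    "transfusion_units",
    "emergency_hysterectomy",
    "age_years",
    "parity",
]

_VITAL_COLUMNS = ("pulse", "sbp", "dbp")
_BOOL_COLUMNS = (
    "died",
    "end_organ_failure",
    "icu_admission",
    "emergency_hysterectomy",
)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}
_NP_TOKENS = {"np", "non-palpable", "nonpalpable"}


class SchemaError(ValueError):
    """The file does not conform to the documented cohort CSV schema."""


class CohortValidationError(ValueError):
    """The data violate a cohort invariant (duplicates, impossible values)."""


def _missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class VitalObservation:
    """One timed measurement of pulse / SBP / DBP for one patient.

    ``non_palpable`` marks observations recorded as non-palpable in the
    source data; the affected vitals are stored as missing.
    """

    minutes_from_entry: int
    pulse: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    non_palpable: bool = False

    def __post_init__(self) -> None:
        if self.minutes_from_entry < 0:
            raise CohortValidationError(
                f"minutes_from_entry must be >= 0, got {self.minutes_from_entry}"
            )
        for name in _VITAL_COLUMNS:
            v = getattr(self, name)
            if _missing(v):
                setattr(self, name, None)
            elif v <= 0:
                raise CohortValidationError(f"{name} must be positive, got {v}")
        if (
            not _missing(self.dbp)
            and not _missing(self.sbp)
            and self.dbp > self.sbp
        ):
            raise CohortValidationError(
                f"dbp ({self.dbp}) exceeds sbp ({self.sbp}) at "
                f"{self.minutes_from_entry} minutes"
            )

    def has_vitals(self) -> bool:
        """True when at least one of pulse or SBP is present."""
        return not (_missing(self.pulse) and _missing(self.sbp))


@dataclass
class PatientRecord:
    """Identity, eligibility fields, observation series, and raw outcomes."""

    patient_id: str
    entry_context: str = "tertiary"
    ebl_ml: float | None = None
    diagnosis: str = "missing"
    observations: list[VitalObservation] = field(default_factory=list)
    died: bool | None = None
    end_organ_failure: bool | None = None
    icu_admission: bool | None = None
    transfusion_units: int | None = None
    emergency_hysterectomy: bool | None = None
    age_years: float | None = None
    parity: int | None = None

    def __post_init__(self) -> None:
        if self.entry_context not in ENTRY_CONTEXTS:
            raise CohortValidationError(
                f"unknown entry_context {self.entry_context!r}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise CohortValidationError(f"unknown diagnosis {self.diagnosis!r}")
        if not _missing(self.ebl_ml) and self.ebl_ml < 0:
            raise CohortValidationError("ebl_ml must be nonnegative")
        if self.transfusion_units is not None and self.transfusion_units < 0:
            raise CohortValidationError("transfusion_units must be nonnegative")
        self.observations.sort(key=lambda o: o.minutes_from_entry)
        minutes = [o.minutes_from_entry for o in self.observations]
        if len(set(minutes)) != len(minutes):
            raise CohortValidationError(
                f"duplicate observation times for patient {self.patient_id}"
            )

    def observations_within(self, window_minutes: int) -> list[VitalObservation]:
        """Observations in the closed window [0, window_minutes]."""
        return [
            o for o in self.observations if o.minutes_from_entry <= window_minutes
        ]

    def has_usable_vitals(self, window_minutes: int = 60) -> bool:
        return any(o.has_vitals() for o in self.observations_within(window_minutes))

    @property
    def entry_observation(self) -> VitalObservation | None:
        """The first (study-entry) observation, or None when there is none."""
        return self.observations[0] if self.observations else None


@dataclass
class Cohort:
    """A list of patient records plus free-text provenance metadata."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id values: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per observation (or one stub row for a
        record with no observations, so no patient is silently dropped)."""
        rows = []
        for r in self.records:
            base = {
                "patient_id": r.patient_id,
                "entry_context": r.entry_context,
                "ebl_ml": r.ebl_ml,
                "diagnosis": r.diagnosis,
                "died": r.died,
                "end_organ_failure": r.end_organ_failure,
                "icu_admission": r.icu_admission,
                "transfusion_units": r.transfusion_units,
                "emergency_hysterectomy": r.emergency_hysterectomy,
                "age_years": r.age_years,
                "parity": r.parity,
            }
            if not r.observations:
                rows.append(
                    {**base, "minutes_from_entry": None, "pulse": None,
                     "sbp": None, "dbp": None, "_non_palpable": False}
                )
            for o in r.observations:
                rows.append(
                    {
                        **base,
                        "minutes_from_entry": o.minutes_from_entry,
                        "pulse": o.pulse,
                        "sbp": o.sbp,
                        "dbp": o.dbp,
                        "_non_palpable": o.non_palpable,
                    }
                )
        df = pd.DataFrame(rows)
        return df[COLUMNS + ["_non_palpable"]].copy()


def _parse_float(token: str, column: str, patient_id: str) -> tuple[float | None, bool]:
    """Parse a numeric cell.  Returns (value, non_palpable_flag)."""
    token = token.strip()
    if token == "":
        return None, False
    if token.lower() in _NP_TOKENS:
        logger.warning(
            "patient %s: %s recorded as non-palpable; stored as missing",
            patient_id, column,
        )
        return None, True
    try:
        return float(token), False
    except ValueError:
        logger.warning(
            "patient %s: unparseable %s value %r treated as missing",
            patient_id, column, token,
        )
        return None, False


def _parse_bool(token: str, column: str, patient_id: str) -> bool | None:
    token = token.strip().lower()
    if token == "":
        return None
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    logger.warning(
        "patient %s: unparseable %s value %r treated as missing",
        patient_id, column, token,
    )
    return None


def read_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read and validate a long-format cohort CSV.

    Rows with unparseable numerics become missing values with a logged
    warning.  Missing mandatory columns raise :class:`SchemaError`;
    duplicate (patient_id, minutes_from_entry) pairs raise
    :class:`CohortValidationError`.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")

    records: list[PatientRecord] = []
    seen_order: list[str] = []
    grouped: dict[str, list[dict]] = {}
    for row in df.to_dict("records"):
        pid = str(row["patient_id"]).strip()
        if pid == "":
            raise CohortValidationError(f"{path}: empty patient_id")
        if pid not in grouped:
            grouped[pid] = []
            seen_order.append(pid)
        grouped[pid].append(row)

    for pid in seen_order:
        rows = grouped[pid]
        first = rows[0]
        ebl, _ = _parse_float(first["ebl_ml"], "ebl_ml", pid)
        age, _ = _parse_float(first["age_years"], "age_years", pid)
        parity, _ = _parse_float(first["parity"], "parity", pid)
        units, _ = _parse_float(first["transfusion_units"], "transfusion_units", pid)
        diagnosis = first["diagnosis"].strip() or "missing"
        context = first["entry_context"].strip() or "tertiary"
        observations = []
        seen_minutes = set()
        for row in rows:
            minutes_raw = str(row["minutes_from_entry"]).strip()
            if minutes_raw == "":
                continue  # stub row for a record without observations
            try:
                minutes = int(float(minutes_raw))
            except ValueError:
                raise CohortValidationError(
                    f"{path}: patient {pid}: bad minutes_from_entry {minutes_raw!r}"
                )
            if minutes in seen_minutes:
                raise CohortValidationError(
                    f"{path}: duplicate (patient_id, minutes_from_entry) "
                    f"({pid}, {minutes})"
                )
            seen_minutes.add(minutes)
            pulse, np_p = _parse_float(row["pulse"], "pulse", pid)
            sbp, np_s = _parse_float(row["sbp"], "sbp", pid)
            dbp, np_d = _parse_float(row["dbp"], "dbp", pid)
            if dbp is not None and sbp is not None and dbp > sbp:
                logger.warning(
                    "patient %s at %d min: dbp %.0f > sbp %.0f; dbp set missing",
                    pid, minutes, dbp, sbp,
                )
                dbp = None
            observations.append(
                VitalObservation(
                    minutes_from_entry=minutes,
                    pulse=pulse,
                    sbp=sbp,
                    dbp=dbp,
                    non_palpable=np_p or np_s or np_d,
                )
            )
        records.append(
            PatientRecord(
                patient_id=pid,
                entry_context=context,
                ebl_ml=ebl,
                diagnosis=diagnosis,
                observations=observations,
                died=_parse_bool(first["died"], "died", pid),
                end_organ_failure=_parse_bool(
                    first["end_organ_failure"], "end_organ_failure", pid
                ),
                icu_admission=_parse_bool(
                    first["icu_admission"], "icu_admission", pid
                ),
                transfusion_units=None if units is None else int(units),
                emergency_hysterectomy=_parse_bool(
                    first["emergency_hysterectomy"], "emergency_hysterectomy", pid
                ),
                age_years=age,
                parity=None if parity is None else int(parity),
            )
        )
    return Cohort(records=records, provenance={"source": str(path)})


def _fmt(value, non_palpable: bool = False) -> str:
    if non_palpable:
        return "NP"
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the long-format CSV schema.

    Missing vitals on a non-palpable observation are written back as the
    ``NP`` token so that read/write round-trips preserve the flag.
    """
    path = Path(path)
    lines = [",".join(COLUMNS)]
    for r in cohort.records:
        base = [
            r.patient_id,
            r.entry_context,
            _fmt(r.ebl_ml),
            r.diagnosis,
        ]
        tail = [
            _fmt(r.died),
            _fmt(r.end_organ_failure),
            _fmt(r.icu_admission),
            _fmt(r.transfusion_units),
            _fmt(r.emergency_hysterectomy),
            _fmt(r.age_years),
            _fmt(r.parity),
        ]
        obs_list = r.observations or [None]
        for o in obs_list:
            if o is None:
                mid = ["", "", "", ""]
            else:
                mid = [
                    _fmt(o.minutes_from_entry),
                    _fmt(o.pulse, o.non_palpable and o.pulse is None),
                    _fmt(o.sbp, o.non_palpable and o.sbp is None),
                    _fmt(o.dbp, o.non_palpable and o.dbp is None),
                ]
            lines.append(",".join(base + mid + tail))
    path.write_text("\n".join(lines) + "\n")


def apply_exclusions(
    cohort: Cohort, window_minutes: int = 60
) -> tuple[Cohort, list[dict]]:
    """Apply the study's exclusion rules; returns (retained cohort, log).

    Excluded are records with no outcome data for death (reason
    ``no_outcome``) and records with no usable vital-sign observation in
    the first hour — including those whose only readings were non-palpable
    (reason ``no_vitals``).  The operation is idempotent.
    """
    retained: list[PatientRecord] = []
    log: list[dict] = []
    for r in cohort.records:
        if r.died is None:
            log.append({"patient_id": r.patient_id, "reason": "no_outcome"})
        elif not r.has_usable_vitals(window_minutes):
            log.append({"patient_id": r.patient_id, "reason": "no_vitals"})
        else:
            retained.append(r)
    if log:
        reasons = pd.Series([e["reason"] for e in log]).value_counts()
        logger.info(
            "excluded %d of %d records (%s)",
            len(log), len(cohort), ", ".join(f"{k}={v}" for k, v in reasons.items()),
        )
    provenance = dict(cohort.provenance)
    provenance["exclusions"] = {
        "input": len(cohort),
        "retained": len(retained),
        "excluded": len(log),
    }
    return Cohort(records=retained, provenance=provenance), log


def eligibility_check(
    record: PatientRecord, ebl_threshold_ml: float = 500.0
) -> bool | None:
    """Study eligibility: EBL above threshold and SBP <= 100 and/or pulse >= 100.

    Entry vitals are taken from the first observation.  Returns ``None``
    (indeterminate) when EBL is missing or when neither entry vital is
    available to evaluate the vital-sign criterion.
    """
    entry = record.entry_observation
    if entry is None:
        raise CohortValidationError(
            f"patient {record.patient_id} has no entry observation"
        )
    if _missing(record.ebl_ml):
        return None
    if record.ebl_ml <= ebl_threshold_ml:
        return False
    sbp_ok = None if _missing(entry.sbp) else entry.sbp <= 100
    pulse_ok = None if _missing(entry.pulse) else entry.pulse >= 100
    if sbp_ok is None and pulse_ok is None:
        return None
    return bool(sbp_ok) or bool(pulse_ok)


def read_entry_cohort(path: str | Path) -> Cohort:
    """Read a wide, entry-vitals-only table (one row per patient).

    Convenience reader for summary-style data with a single measurement:
    the row's pulse/SBP/DBP become one observation at minute 0.  The file
    must contain all cohort columns except ``minutes_from_entry``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in COLUMNS if c != "minutes_from_entry"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")
    df = df.copy()
    df["minutes_from_entry"] = "0"
    import tempfile

    with tempfile.TemporaryDirectory() as tmpdir:
        tmp = Path(tmpdir) / "entry_long.csv"
        df[COLUMNS].to_csv(tmp, index=False)
        cohort = read_cohort(tmp)
    cohort.provenance["source"] = str(path)
    return cohort
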