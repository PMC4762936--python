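"""Cohort CSV schema, exclusion rules, and eligibility."""

import logging

import pytest

from vsalert import (
    Cohort,
    CohortValidationError,
    PatientRecord,
    SchemaError,
    VitalObservation,
    apply_exclusions,
    eligibility_check,
    read_cohort,
    read_entry_cohort,
    write_cohort,
)

HEADER = (
    "patient_id,entry_context,ebl_ml,diagnosis,minutes_from_entry,pulse,sbp,"
    "dbp,died,end_organ_failure,icu_admission,transfusion_units,"
    "emergency_hysterectomy,age_years,parity"
)


def _write(tmp_path, rows, header=HEADER, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def _record(pid="A", **kwargs):
    defaults = dict(
        observations=[VitalObservation(0, pulse=110.0, sbp=90.0, dbp=60.0)],
        died=False,
        ebl_ml=1000.0,
    )
    defaults.update(kwargs)
    return PatientRecord(patient_id=pid, **defaults)


class TestReadWrite:
    def test_two_patient_round_trip(self, tmp_path):
        """read_cohort of a well-formed file yields both records, and
        write_cohort/read_cohort is the identity field-for-field."""
        path = _write(
            tmp_path,
            [
                "A,tertiary,1000,uterine_atony,0,110,95,60,0,0,0,2,0,28,2",
                "A,tertiary,1000,uterine_atony,15,120,85,,0,0,0,2,0,28,2",
                "B,phc,800,ectopic,0,105,,,1,1,1,6,0,31,1",
            ],
        )
        cohort = read_cohort(path)
        assert len(cohort) == 2
        a = cohort.records[0]
        assert [o.minutes_from_entry for o in a.observations] == [0, 15]
        assert a.observations[1].dbp is None
        assert cohort.records[1].died is True

        out = tmp_path / "again.csv"
        write_cohort(cohort, out)
        cohort2 = read_cohort(out)
        assert cohort.records == cohort2.records

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        header = HEADER.replace("pulse,", "")
        path = _write(
            tmp_path, ["A,tertiary,1000,other,0,95,60,0,0,0,2,0,28,2"], header
        )
        with pytest.raises(SchemaError, match="pulse"):
            read_cohort(path)

    def test_non_palpable_token_parses_to_missing_with_flag(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            ["A,tertiary,1000,other,0,NP,NP,,0,0,0,0,0,,"],
        )
        with caplog.at_level(logging.WARNING):
            cohort = read_cohort(path)
        obs = cohort.records[0].observations[0]
        assert obs.pulse is None and obs.sbp is None
        assert obs.non_palpable
        assert "non-palpable" in caplog.text
        # NP token survives a write/read cycle
        out = tmp_path / "np.csv"
        write_cohort(cohort, out)
        assert read_cohort(out).records[0].observations[0].non_palpable

    def test_unparseable_numeric_becomes_missing_with_warning(
        self, tmp_path, caplog
    ):
        path = _write(
            tmp_path,
            ["A,tertiary,1000,other,0,garbled,90,,0,0,0,0,0,,"],
        )
        with caplog.at_level(logging.WARNING):
            cohort = read_cohort(path)
        assert cohort.records[0].observations[0].pulse is None
        assert "garbled" in caplog.text

    def test_duplicate_patient_time_is_validation_error(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "A,tertiary,1000,other,0,110,90,,0,0,0,0,0,,",
                "A,tertiary,1000,other,0,112,88,,0,0,0,0,0,,",
            ],
        )
        with pytest.raises(CohortValidationError, match="duplicate"):
            read_cohort(path)

    def test_dbp_above_sbp_dropped_with_warning(self, tmp_path, caplog):
        path = _write(
            tmp_path, ["A,tertiary,1000,other,0,110,80,95,0,0,0,0,0,,"]
        )
        with caplog.at_level(logging.WARNING):
            cohort = read_cohort(path)
        obs = cohort.records[0].observations[0]
        assert obs.sbp == 80 and obs.dbp is None

    def test_entry_wide_reader(self, tmp_path):
        header = HEADER.replace("minutes_from_entry,", "")
        path = _write(
            tmp_path,
            ["A,phc,900,previa,118,92,58,0,0,0,0,0,25,1"],
            header,
            name="entry.csv",
        )
        cohort = read_entry_cohort(path)
        obs = cohort.records[0].observations[0]
        assert obs.minutes_from_entry == 0
        assert (obs.pulse, obs.sbp, obs.dbp) == (118.0, 92.0, 58.0)


class TestInvariants:
    def test_duplicate_patient_ids_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate patient_id"):
            Cohort(records=[_record("A"), _record("A")])

    def test_observation_validation(self):
        with pytest.raises(CohortValidationError):
            VitalObservation(0, pulse=-5.0)
        with pytest.raises(CohortValidationError):
            VitalObservation(0, sbp=80.0, dbp=90.0)
        with pytest.raises(CohortValidationError):
            VitalObservation(-15, pulse=100.0)

    def test_observations_sorted_on_construction(self):
        rec = _record(
            observations=[
                VitalObservation(30, pulse=100.0),
                VitalObservation(0, pulse=110.0),
            ]
        )
        assert [o.minutes_from_entry for o in rec.observations] == [0, 30]


class TestExclusions:
    def test_reasons_and_count_conservation(self):
        cohort = Cohort(
            records=[
                _record("ok"),
                _record("no_vitals", observations=[VitalObservation(0)]),
                _record(
                    "late_only",
                    observations=[VitalObservation(75, pulse=120.0, sbp=80.0)],
                ),
                _record("no_outcome", died=None),
            ]
        )
        retained, log = apply_exclusions(cohort)
        assert len(retained) + len(log) == len(cohort)
        reasons = {e["patient_id"]: e["reason"] for e in log}
        assert reasons == {
            "no_vitals": "no_vitals",
            "late_only": "no_vitals",
            "no_outcome": "no_outcome",
        }

    def test_idempotent(self):
        cohort = Cohort(
            records=[_record("ok"), _record("gone", died=None)]
        )
        once, _ = apply_exclusions(cohort)
        twice, log2 = apply_exclusions(once)
        assert [r.patient_id for r in twice.records] == ["ok"]
        assert log2 == []

    def test_study_scale_analogue(self):
        """A cohort with 1 missing-outcome and 2 vital-less records among 10
        retains exactly 7 — the same bookkeeping that takes 967 to 958."""
        records = [_record(f"P{i}") for i in range(7)]
        records.append(_record("x1", died=None))
        records.append(_record("x2", observations=[VitalObservation(0)]))
        records.append(
            _record(
                "x3",
                observations=[
                    VitalObservation(0, non_palpable=True)
                ],
            )
        )
        retained, log = apply_exclusions(Cohort(records=records))
        assert len(retained) == 7
        assert sum(e["reason"] == "no_outcome" for e in log) == 1
        assert sum(e["reason"] == "no_vitals" for e in log) == 2


class TestEligibility:
    @pytest.mark.parametrize(
        "ebl,sbp,pulse,threshold,expected",
        [
            (1000.0, 90.0, 80.0, 750.0, True),   # SBP criterion alone
            (1000.0, 120.0, 90.0, 750.0, False), # neither vital criterion
            (400.0, 80.0, 120.0, 500.0, False),  # EBL below threshold
            (1000.0, 120.0, 110.0, 500.0, True), # pulse criterion alone
            (None, 90.0, 120.0, 500.0, None),    # missing EBL: indeterminate
        ],
    )
    def test_rule(self, ebl, sbp, pulse, threshold, expected):
        rec = _record(
            ebl_ml=ebl,
            observations=[VitalObservation(0, pulse=pulse, sbp=sbp)],
        )
        assert eligibility_check(rec, ebl_threshold_ml=threshold) is expected

    def test_missing_entry_vitals_indeterminate(self):
        rec = _record(observations=[VitalObservation(0)])
        assert eligibility_check(rec, 500.0) is None
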