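"""Domain types, validation and interchange round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from pimscreen.cohort import (
    Cohort, CohortValidationError, LabPanel, MedicationOrder, PatientRecord,
    medication_count_category, read_cohort, write_cohort,
)
from pimscreen.recipes import med


def _patient(pid="P1", n_meds=1, age=70, **kw):
    meds = tuple(
        med(code, 10, days=30)
        for code in ["N02BE01", "A11BA01", "A12AA04", "B03BB01", "A11CC05",
                     "A11GA01", "A11HA02", "A12BA01", "A10AB01", "B03AA07",
                     "C10AA01", "A02BA03"][:n_meds]
    )
    return PatientRecord(patient_id=pid, age_years=age, sex="male",
                         medications=meds, **kw)


class TestValidation:
    def test_age_below_inclusion_threshold_rejected(self):
        with pytest.raises(CohortValidationError, match="below inclusion threshold 60"):
            _patient(age=59)

    def test_empty_medication_list_rejected(self):
        with pytest.raises(CohortValidationError, match="at least one"):
            PatientRecord(patient_id="P1", age_years=70, sex="male", medications=())

    def test_unknown_condition_code_named_in_error(self):
        with pytest.raises(CohortValidationError, match="made_up_disease"):
            PatientRecord(patient_id="P1", age_years=70, sex="male",
                          conditions={"made_up_disease"},
                          medications=(med("N02BE01", 500),))

    @pytest.mark.parametrize("code", ["B01AC6", "b01ac06", "B01-AC06", "12AB34"])
    def test_malformed_atc_code_rejected(self, code):
        with pytest.raises(CohortValidationError, match="ATC"):
            MedicationOrder(atc_code=code)

    def test_unknown_dose_unit_rejected_not_converted(self):
        with pytest.raises(CohortValidationError, match="unit"):
            MedicationOrder(atc_code="N02BE01", daily_dose=1, dose_unit="mcg")

    def test_nonpositive_lab_value_rejected(self):
        with pytest.raises(CohortValidationError, match="strictly positive"):
            LabPanel(egfr=0)

    def test_duplicate_patient_id_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate"):
            Cohort(patients=(_patient("P1"), _patient("P1")))

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortValidationError):
            Cohort(patients=())


class TestRoundTrip:
    def test_json_round_trip_small(self, tmp_path):
        cohort = Cohort(patients=(_patient("A", 3), _patient("B", 7)))
        path = tmp_path / "c.json"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert back.patients == cohort.patients
        assert [p.patient_id for p in back] == ["A", "B"]  # order preserved

    def test_csv_round_trip_small(self, tmp_path):
        patient = PatientRecord(
            patient_id="X", age_years=81, sex="female",
            conditions={"hypertension", "copd"},
            labs=LabPanel(egfr=42.5, free_t4_status="normal"),
            medications=(med("C03CA01", 40, days=60),
                         med("H02AB09", 100, route="parenteral", days=5, prn=True)),
        )
        cohort = Cohort(patients=(patient,))
        write_cohort(cohort, tmp_path / "c", format="csv")
        back = read_cohort(tmp_path / "c", format="csv")
        assert back.patients == cohort.patients

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_reference_cohort_round_trip(self, fixture_cohort, tmp_path, fmt):
        target = tmp_path / ("c.json" if fmt == "json" else "c")
        write_cohort(fixture_cohort, target, format=fmt)
        back = read_cohort(target, format=fmt)
        assert back.patients == fixture_cohort.patients

    def test_missing_field_names_record(self, tmp_path):
        (tmp_path / "bad.json").write_text('{"patients": [{"age_years": 70}]}')
        with pytest.raises(CohortValidationError, match="record 0"):
            read_cohort(tmp_path / "bad.json")


class TestMedicationBands:
    @pytest.mark.parametrize("n,expected", [
        (1, "low"), (3, "low"), (4, "low"),
        (5, "mid"), (6, "mid"), (9, "mid"),
        (10, "high"), (12, "high"),
    ])
    def test_band_boundaries(self, n, expected):
        assert medication_count_category(_patient(n_meds=n)) == expected

    def test_bands_partition_reference_cohort(self, fixture_cohort):
        bands = [medication_count_category(p) for p in fixture_cohort]
        assert len(bands) == len(fixture_cohort)
        assert set(bands) <= {"low", "mid", "high"}
        counts = {b: bands.count(b) for b in ("low", "mid", "high")}
        assert sum(counts.values()) == len(fixture_cohort)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=60, max_value=99),
       st.integers(min_value=1, max_value=8),
       st.sampled_from(["male", "female"]))
def test_round_trip_property(tmp_path_factory, age, n_meds, sex):
    """Arbitrary valid patients survive a JSON write/read unchanged."""
    p = PatientRecord(
        patient_id=f"H{age}{n_meds}{sex}", age_years=age, sex=sex,
        conditions={"hypertension"} if age % 2 else frozenset(),
        labs=LabPanel(egfr=float(30 + age)),
        medications=tuple(
            med(c, 10.0 + i, days=i + 1)
            for i, c in enumerate(["N02BE01", "A11BA01", "A12AA04", "B03BB01",
                                   "A11CC05", "A11GA01", "A11HA02", "A12BA01"][:n_meds])
        ),
    )
    cohort = Cohort(patients=(p,))
    path = tmp_path_factory.mktemp("rt") / "c.json"
    write_cohort(cohort, path)
    assert read_cohort(path).patients == cohort.patients
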