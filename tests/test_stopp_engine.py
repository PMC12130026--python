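"""Rule-engine behaviour: per-criterion fixtures, tri-state evaluation,
conservation and order-invariance."""

import pytest

from pimscreen.cohort import Cohort, LabPanel, PatientRecord
from pimscreen.engine import (
    NOT_EVALUABLE, NOT_TRIGGERED, TRIGGERED, evaluate_criterion, get_criteria,
    screen_cohort, screen_patient, tally,
)
from pimscreen.recipes import TRIGGER_RECIPES, med
from pimscreen.simulate import CohortSpec, generate

ALL_IDS = sorted(get_criteria())
LAB_DEPENDENT = sorted(cid for cid, r in TRIGGER_RECIPES.items() if r.lab_dependent)


def test_registry_is_complete():
    assert len(ALL_IDS) == 133
    sections = {cid[0] for cid in ALL_IDS}
    assert sections == set("ABCDEFGHIJKLM")


def test_unknown_criterion_id_raises():
    with pytest.raises(KeyError, match="Z9"):
        evaluate_criterion("Z9", TRIGGER_RECIPES["A1"].patient())


@pytest.mark.parametrize("cid", ALL_IDS)
def test_criterion_fires_on_its_canonical_constellation(cid):
    recipe = TRIGGER_RECIPES[cid]
    outcome, flags = evaluate_criterion(cid, recipe.patient())
    assert outcome.status == TRIGGERED
    assert flags and all(f.criterion_id == cid for f in flags)
    assert all(f.atc_codes for f in flags)


@pytest.mark.parametrize("cid", ALL_IDS)
def test_criterion_silent_without_its_subject_drug(cid):
    recipe = TRIGGER_RECIPES[cid]
    outcome, flags = evaluate_criterion(cid, recipe.patient_without_subject())
    assert outcome.status == NOT_TRIGGERED
    assert flags == []


@pytest.mark.parametrize("cid", LAB_DEPENDENT)
def test_missing_lab_yields_not_evaluable(cid):
    recipe = TRIGGER_RECIPES[cid]
    outcome, flags = evaluate_criterion(cid, recipe.patient_without_labs())
    assert outcome.status == NOT_EVALUABLE
    assert flags == []
    assert outcome.missing_inputs  # names the absent measurements


class TestSpotExamples:
    def test_nsaid_with_low_egfr_triggers_renal_rule(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          labs=LabPanel(egfr=40),
                          medications=(med("M01AB05", 75, days=30),))
        outcome, _ = evaluate_criterion("E4", p)
        assert outcome.status == TRIGGERED

    def test_nsaid_without_egfr_is_not_evaluable_naming_egfr(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          medications=(med("M01AB05", 75, days=30),))
        outcome, _ = evaluate_criterion("E4", p)
        assert outcome.status == NOT_EVALUABLE
        assert outcome.missing_inputs == ("egfr",)

    def test_high_dose_long_term_aspirin_triggers(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          conditions={"coronary_artery_disease"},
                          medications=(med("B01AC06", 150, days=120),))
        outcome, _ = evaluate_criterion("C1", p)
        assert outcome.status == TRIGGERED

    def test_low_dose_aspirin_does_not_trigger_dose_rule(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          conditions={"coronary_artery_disease"},
                          medications=(med("B01AC06", 75, days=120),))
        outcome, _ = evaluate_criterion("C1", p)
        assert outcome.status == NOT_TRIGGERED

    def test_pheniramine_for_allergy_yields_exactly_one_flag(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          conditions={"allergy_pruritus"},
                          medications=(med("D04AA16", 25, days=7),))
        flags = screen_patient(p)
        assert [f.criterion_id for f in flags] == ["D24"]

    def test_innocuous_patient_has_no_flags(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          medications=(med("N02BE01", 1000, days=10),))
        assert screen_patient(p) == []

    def test_two_concurrent_regular_nsaids_flag_duplicate_class(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          medications=(med("M01AB05", 100, days=30),
                                       med("M01AE01", 1200, days=30)))
        flags = screen_patient(p)
        a3 = [f for f in flags if f.criterion_id == "A3"]
        assert len(a3) == 1
        assert set(a3[0].atc_codes) == {"M01AB05", "M01AE01"}

    def test_prn_orders_do_not_count_toward_duplicate_class(self):
        p = PatientRecord(patient_id="X", age_years=72, sex="male",
                          medications=(med("M01AB05", 100, days=30),
                                       med("M01AE01", 1200, days=30, prn=True)))
        outcome, _ = evaluate_criterion("A3", p)
        assert outcome.status == NOT_TRIGGERED

    def test_qtc_threshold_is_sex_specific(self):
        def patient(sex):
            return PatientRecord(patient_id="X", age_years=72, sex=sex,
                                 labs=LabPanel(qtc_ms=460),
                                 medications=(med("N05AD01", 2, days=10),))
        assert evaluate_criterion("B15", patient("male"))[0].status == TRIGGERED
        assert evaluate_criterion("B15", patient("female"))[0].status == NOT_TRIGGERED


class TestConservationAndInvariance:
    def test_flag_counts_conserved_across_tally_axes(self, fixture_flags):
        total = len(fixture_flags)
        assert tally(fixture_flags, by="criterion").sum() == total
        assert tally(fixture_flags, by="system").sum() == total
        assert tally(fixture_flags, by="drug").sum() == total
        per_patient = tally(fixture_flags, by="patient")
        assert (per_patient.index * per_patient).sum() == total
        assert per_patient.sum() == fixture_flags.n_patients

    def test_unknown_tally_axis_raises(self, fixture_flags):
        with pytest.raises(ValueError, match="axis"):
            tally(fixture_flags, by="ward")

    def test_screening_is_order_invariant(self, fixture_cohort, fixture_flags):
        permuted = Cohort(patients=tuple(reversed(fixture_cohort.patients)))
        flags2 = screen_cohort(permuted)
        key = lambda f: (f.patient_id, f.criterion_id, f.atc_codes)
        assert sorted(map(key, fixture_flags.flags)) == sorted(map(key, flags2.flags))

    def test_conservation_on_random_cohorts(self):
        for seed in range(20):
            cohort = generate(CohortSpec(n=15, seed=seed))
            table = screen_cohort(cohort)
            assert tally(table, by="criterion").sum() == len(table)
            assert tally(table, by="system").sum() == len(table)

    def test_adding_inert_medication_never_changes_flags(self, fixture_cohort):
        inert = med("A11GA01", 500, days=30)
        for p in fixture_cohort.patients[:40]:
            if any(m.atc_code == inert.atc_code for m in p.medications):
                continue
            before = sorted((f.criterion_id, f.atc_codes) for f in screen_patient(p))
            grown = PatientRecord(
                patient_id=p.patient_id, age_years=p.age_years, sex=p.sex,
                conditions=p.conditions, labs=p.labs,
                medications=p.medications + (inert,),
            )
            after = sorted((f.criterion_id, f.atc_codes) for f in screen_patient(grown))
            assert before == after

    def test_screening_is_deterministic(self):
        recipe = TRIGGER_RECIPES["D24"]
        p = recipe.patient()
        assert screen_patient(p) == screen_patient(p)
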