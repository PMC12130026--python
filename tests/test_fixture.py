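"""The deterministic reference cohort reproduces every published margin."""

from pimscreen import reference_data as ref
from pimscreen.analytics import age_band, prevalence
from pimscreen.cohort import medication_count_category
from pimscreen.engine import tally


def test_cohort_size_and_flag_total(fixture_cohort, fixture_flags):
    assert len(fixture_cohort) == ref.COHORT_N
    assert len(fixture_flags) == ref.TOTAL_PIM_INSTANCES


def test_per_criterion_counts_exact(fixture_flags):
    assert tally(fixture_flags, by="criterion").to_dict() == ref.CRITERION_COUNTS


def test_per_system_counts_exact(fixture_flags):
    assert tally(fixture_flags, by="system").to_dict() == ref.SYSTEM_COUNTS


def test_flagged_patients_and_distribution(fixture_flags):
    assert len(fixture_flags.flagged_patients()) == ref.FLAGGED_PATIENTS
    dist = tally(fixture_flags, by="patient").to_dict()
    assert {k: v for k, v in dist.items() if k > 0} == ref.PIMS_PER_PATIENT
    assert dist[0] == ref.COHORT_N - ref.FLAGGED_PATIENTS


def test_prevalence_in_documented_window(fixture_flags):
    prop, pct = prevalence(fixture_flags)
    assert 56.6 <= pct <= 56.7  # published 56.6; computed 255/450 = 56.67


def test_leading_drug_attributions(fixture_flags):
    drugs = tally(fixture_flags, by="drug").to_dict()
    for code, n in ref.TOP_DRUG_COUNTS.items():
        assert drugs[code] == n, code
    assert max(drugs, key=drugs.get) == "B01AC06"


def test_demographic_marginals(fixture_cohort):
    sexes = [p.sex for p in fixture_cohort]
    assert sexes.count("male") == ref.SEX_COUNTS["male"]
    bands = [age_band(p.age_years) for p in fixture_cohort]
    assert {b: bands.count(b) for b in ref.AGE_BAND_COUNTS} == ref.AGE_BAND_COUNTS
    meds = [medication_count_category(p) for p in fixture_cohort]
    assert {b: meds.count(b) for b in ref.MED_BAND_COUNTS} == ref.MED_BAND_COUNTS


def test_construction_is_cached_and_stable(fixture_cohort):
    from pimscreen.fixture import generate_reference_fixture
    assert generate_reference_fixture() is fixture_cohort
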