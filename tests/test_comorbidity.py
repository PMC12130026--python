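"""Charlson index scoring against an independently coded weight oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from pimscreen.comorbidity import band_of, cci_score, comorbidity_category

#: Independent oracle: the original Charlson weights, coded directly as a
#: condition -> (weight, exclusivity group) map.  Within a group only the
#: highest weight counts.
_ORACLE = {
    "mi_history": (1, "mi"),
    "heart_failure": (1, "chf"),
    "heart_failure_preserved_ef": (1, "chf"),
    "heart_failure_nyha_3_4": (1, "chf"),
    "peripheral_vascular_disease": (1, "pvd"),
    "aortic_aneurysm": (1, "pvd"),
    "stroke": (1, "cvd"),
    "cerebrovascular_disease": (1, "cvd"),
    "dementia": (1, "dem"),
    "lewy_body_dementia": (1, "dem"),
    "copd": (1, "pulm"),
    "connective_tissue_disease": (1, "ctd"),
    "rheumatoid_arthritis": (1, "ctd"),
    "peptic_ulcer_disease": (1, "pud"),
    "liver_disease_mild": (1, "liver"),
    "liver_disease_severe": (3, "liver"),
    "diabetes_type2": (1, "dm"),
    "diabetes_complicated": (2, "dm"),
    "hemiplegia": (2, "hemi"),
    "renal_failure": (2, "renal"),
    "nephrotic_syndrome": (2, "renal"),
    "cancer": (2, "tumor"),
    "breast_cancer": (2, "tumor"),
    "metastatic_cancer": (6, "tumor"),
    "aids": (6, "aids"),
}


def oracle_score(conditions) -> int:
    best: dict[str, int] = {}
    for c in conditions:
        if c in _ORACLE:
            w, g = _ORACLE[c]
            best[g] = max(best.get(g, 0), w)
    return sum(best.values())


class TestScore:
    def test_no_conditions_scores_zero(self):
        r = cci_score(frozenset())
        assert (r.score, r.band) == (0, "none")
        assert r.contributing_conditions == ()

    def test_mi_plus_diabetes_is_mild(self):
        r = cci_score({"mi_history", "diabetes_type2"})
        assert (r.score, r.band) == (2, "mild")

    def test_metastatic_tumor_alone_is_severe(self):
        r = cci_score({"metastatic_cancer"})
        assert r.score == 6
        assert r.band == "severe"

    def test_graded_pairs_count_once_at_higher_weight(self):
        assert cci_score({"diabetes_type2", "diabetes_complicated"}).score == 2
        assert cci_score({"cancer", "metastatic_cancer"}).score == 6
        assert cci_score({"liver_disease_mild", "liver_disease_severe"}).score == 3

    def test_non_index_conditions_contribute_zero(self):
        assert cci_score({"hypertension", "insomnia", "mild_pain"}).score == 0

    @settings(max_examples=200, deadline=None)
    @given(st.sets(st.sampled_from(sorted(_ORACLE))))
    def test_matches_independent_weight_oracle(self, conditions):
        assert cci_score(conditions).score == oracle_score(conditions)

    @settings(max_examples=100, deadline=None)
    @given(st.sets(st.sampled_from(sorted(_ORACLE))),
           st.sampled_from(sorted(_ORACLE)))
    def test_score_monotone_under_adding_conditions(self, conditions, extra):
        assert cci_score(conditions | {extra}).score >= cci_score(conditions).score


class TestBands:
    @pytest.mark.parametrize("score,band", [
        (0, "none"), (1, "mild"), (2, "mild"),
        (3, "moderate"), (4, "moderate"), (5, "severe"), (11, "severe"),
    ])
    def test_band_boundaries(self, score, band):
        assert band_of(score) == band


class TestComorbidityCategory:
    def test_no_chronic_conditions(self):
        assert comorbidity_category(frozenset()) == "none"
        assert comorbidity_category({"insomnia", "mild_pain"}) == "none"

    def test_single_chronic_condition(self):
        assert comorbidity_category({"hypertension"}) == "comorbidity"

    def test_two_chronic_conditions(self):
        assert comorbidity_category({"hypertension", "diabetes_type2"}) == "multimorbidity"

    def test_graded_variants_of_one_disease_count_once(self):
        assert comorbidity_category({"coronary_artery_disease", "mi_history"}) == "comorbidity"
        assert comorbidity_category({"diabetes_type2", "diabetes_complicated"}) == "comorbidity"
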