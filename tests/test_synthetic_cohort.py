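"""Synthetic generator: determinism, marginal convergence, planted effects."""

import math

import numpy as np
import pytest

from pimscreen.analytics import fit_multivariable_logistic
from pimscreen.cohort import write_cohort
from pimscreen.simulate import (
    CohortSpec, InfeasibleSpecError, calibrate_intercept, generate,
    plant_effects, simulate_analysis_frame,
)


class TestSpecValidation:
    def test_zero_size_rejected(self):
        with pytest.raises(InfeasibleSpecError, match="positive"):
            generate(CohortSpec(n=0))

    def test_trigger_rate_with_zero_condition_prevalence_names_conflict(self):
        spec = CohortSpec(n=10, condition_prevalences={"copd": 0.0},
                          criterion_trigger_rates={"G2": 0.1})
        with pytest.raises(InfeasibleSpecError, match="G2.*copd"):
            generate(spec)

    def test_age_band_probs_must_sum_to_one(self):
        with pytest.raises(InfeasibleSpecError, match="sum to 1"):
            generate(CohortSpec(n=10, age_band_probs={"60-64": 0.5}))

    def test_unknown_criterion_rejected(self):
        with pytest.raises(InfeasibleSpecError, match="Z9"):
            generate(CohortSpec(n=10, criterion_trigger_rates={"Z9": 0.1}))


class TestDeterminism:
    def test_identical_spec_and_seed_byte_identical(self, tmp_path):
        spec = CohortSpec(n=60, seed=11)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_cohort(generate(spec), p1)
        write_cohort(generate(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate(CohortSpec(n=60, seed=1))
        b = generate(CohortSpec(n=60, seed=2))
        assert a.patients != b.patients


class TestMarginalConvergence:
    def test_male_fraction_converges(self):
        cohort = generate(CohortSpec(n=10_000, seed=5))
        frac = sum(p.sex == "male" for p in cohort) / len(cohort)
        assert abs(frac - 0.553) < 0.02

    def test_condition_prevalences_converge(self):
        cohort = generate(CohortSpec(n=10_000, seed=6))
        htn = sum("hypertension" in p.conditions for p in cohort) / len(cohort)
        dm = sum("diabetes_type2" in p.conditions for p in cohort) / len(cohort)
        assert abs(htn - 0.496) < 0.02
        assert abs(dm - 0.338) < 0.02

    def test_every_generated_record_is_valid(self):
        cohort = generate(CohortSpec(n=300, seed=7))
        assert len(cohort) == 300
        assert all(p.age_years >= 60 and p.medications for p in cohort)


class TestPlantedEffects:
    def test_null_effects_recover_unit_odds_ratios(self):
        spec = CohortSpec(n=20_000, seed=8,
                          planted_effects={}, intercept=0.0)
        df = simulate_analysis_frame(spec)
        fit = fit_multivariable_logistic(df)
        for name, r in fit.levels.items():
            assert 0.85 < r.odds_ratio < 1.18, name

    def test_large_n_consistency_of_headline_effect(self):
        spec = CohortSpec(n=50_000, seed=9)
        df = simulate_analysis_frame(spec)
        fit = fit_multivariable_logistic(df)
        assert 2.7 < fit.levels["med_band=mid"].odds_ratio < 3.1  # planted 2.89

    def test_intercept_calibration_hits_target_marginal(self):
        spec = CohortSpec(n=50_000, seed=10)
        assert -5 < calibrate_intercept(spec) < 0
        df = simulate_analysis_frame(spec)
        assert abs(df["pim"].mean() - 0.566) < 0.015

    def test_plant_effects_deterministic_given_rng(self):
        spec = CohortSpec(n=500, seed=12)
        df = simulate_analysis_frame(spec).drop(columns="pim")
        a = plant_effects(df, spec, np.random.default_rng(3))
        b = plant_effects(df, spec, np.random.default_rng(3))
        assert (a == b).all()
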