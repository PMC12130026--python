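"""Odds ratios, bivariate screen, logistic model, sample size, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from pimscreen.analytics import (
    ConvergenceError, TwoByTwoTable, bivariate_screen, crude_or,
    fit_multivariable_logistic, prevalence, round_half_up, sample_size,
    summarize_cohort,
)
from pimscreen import reference_data as ref
from pimscreen.engine import FlagTable, PIMFlag


def _flag(pid, cid="D24", code="D04AA16"):
    return PIMFlag(patient_id=pid, criterion_id=cid, atc_codes=(code,),
                   system_group="central_nervous_system")


class TestCrudeOR:
    @pytest.mark.parametrize("cells,expected", sorted(
        (ref.TABLE_2X2[k], v) for k, v in ref.PUBLISHED_CRUDE_OR.items()
    ))
    def test_reproduces_published_point_estimates(self, cells, expected):
        r = crude_or(TwoByTwoTable(*cells))
        assert round_half_up(r.odds_ratio, 2) == expected

    def test_woolf_ci_for_medication_band(self):
        r = crude_or(TwoByTwoTable(184, 125, 30, 61))
        assert abs(r.ci_low - 1.82) <= 0.01
        assert abs(r.ci_high - 4.90) <= 0.01

    def test_balanced_table_gives_unit_or_with_symmetric_ci(self):
        r = crude_or(TwoByTwoTable(10, 10, 10, 10))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)

    def test_zero_cell_rejected_with_correction_hint(self):
        with pytest.raises(ValueError, match="continuity"):
            crude_or(TwoByTwoTable(5, 0, 3, 7))

    def test_continuity_correction_option(self):
        r = crude_or(TwoByTwoTable(5, 0, 3, 7), continuity_correction=True)
        assert r.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            TwoByTwoTable(0, 0, 0, 0)


class TestSingleCovariateIdentity:
    def test_logistic_fit_equals_crude_or(self):
        t = TwoByTwoTable(*ref.TABLE_2X2["meds_high"])
        rows = pd.DataFrame(
            [{"pim": 1, "sex": "male"}] * t.a + [{"pim": 0, "sex": "male"}] * t.b
            + [{"pim": 1, "sex": "female"}] * t.c + [{"pim": 0, "sex": "female"}] * t.d
        )
        fit = fit_multivariable_logistic(rows, covariates=("sex",))
        assert fit.levels["sex=male"].odds_ratio == pytest.approx(
            crude_or(t).odds_ratio, abs=1e-6)

    def test_separation_raises_diagnostic(self):
        rows = pd.DataFrame(
            [{"pim": 1, "sex": "male"}] * 20 + [{"pim": 0, "sex": "female"}] * 20
        )
        with pytest.raises(ConvergenceError):
            fit_multivariable_logistic(rows, covariates=("sex",))


class TestBivariateScreen:
    def test_published_tables_select_medication_and_comorbidity(self):
        selected, pvals = bivariate_screen(ref.KX2_TABLES)
        assert set(selected) == {"med_band", "comorbidity"}
        assert pvals["sex"] > 0.25 and pvals["age_band"] > 0.25

    def test_exposure_identical_to_outcome_selected(self):
        selected, pvals = bivariate_screen({"x": [[50, 0], [0, 50]]})
        assert selected == ["x"] and pvals["x"] < 1e-10

    def test_type_one_rate_near_nominal_under_independence(self):
        rng = np.random.default_rng(1234)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            exp = rng.random(400) < 0.5
            out = rng.random(400) < 0.5
            table = [[int((~exp & out).sum()), int((~exp & ~out).sum())],
                     [int((exp & out).sum()), int((exp & ~out).sum())]]
            selected, _ = bivariate_screen({"x": table})
            hits += bool(selected)
        assert 0.18 < hits / n_sim < 0.32  # nominal 0.25

    def test_sparse_expected_cell_uses_exact_fallback(self):
        selected, pvals = bivariate_screen({"x": [[1, 0], [0, 400]]})
        assert 0 <= pvals["x"] <= 1


class TestSampleSize:
    def test_published_study_inputs_give_425(self):
        assert sample_size(**ref.SAMPLE_SIZE_INPUTS) == ref.REQUIRED_SAMPLE

    def test_half_prevalence_no_attrition(self):
        assert sample_size(0.5, 0.05, z=1.96) == 385  # ceil(384.16)

    def test_degenerate_precision_floors_at_one(self):
        assert sample_size(0.5, 1e6) == 1

    def test_monotone_in_precision_and_prevalence(self):
        assert sample_size(0.64, 0.04) >= sample_size(0.64, 0.05)
        assert sample_size(0.5, 0.05) >= sample_size(0.64, 0.05)
        assert sample_size(0.64, 0.05, attrition=0.2) >= sample_size(0.64, 0.05)

    @pytest.mark.parametrize("kw", [
        {"p": 0.0, "d": 0.05}, {"p": 1.2, "d": 0.05},
        {"p": 0.5, "d": 0.0}, {"p": 0.5, "d": 0.05, "attrition": 1.0},
    ])
    def test_out_of_range_inputs_rejected(self, kw):
        with pytest.raises(ValueError):
            sample_size(**kw)


class TestPrevalence:
    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            prevalence(FlagTable(n_patients=0))

    def test_no_flags_gives_zero(self):
        assert prevalence(FlagTable(n_patients=450)) == (0.0, 0.0)

    def test_all_flagged_gives_hundred(self):
        t = FlagTable(flags=[_flag(f"P{i}") for i in range(10)], n_patients=10)
        assert prevalence(t) == (1.0, 100.0)

    def test_display_rounding_is_half_up_to_one_decimal(self):
        t = FlagTable(flags=[_flag(f"P{i}") for i in range(255)], n_patients=450)
        prop, pct = prevalence(t)
        assert prop == pytest.approx(255 / 450)
        assert pct == 56.7  # 56.666... rounds half-up to one decimal


class TestSummaries:
    def test_identical_ages_collapse_iqr(self, fixture_cohort):
        from pimscreen.cohort import Cohort, PatientRecord
        from pimscreen.recipes import med
        patients = tuple(
            PatientRecord(patient_id=f"P{i}", age_years=70, sex="male",
                          medications=(med("N02BE01", 500),))
            for i in range(5)
        )
        s = summarize_cohort(Cohort(patients=patients))
        assert s["age_median_iqr"] == "70 (70-70)"

    def test_med_band_counts_partition_cohort(self, fixture_cohort):
        s = summarize_cohort(fixture_cohort)
        assert sum(s["med_band_counts"].values()) == s["n"]
        assert sum(s["sex_counts"].values()) == s["n"]
        assert sum(s["age_band_counts"].values()) == s["n"]

    def test_top_drug_of_reference_cohort(self, fixture_cohort, fixture_flags):
        s = summarize_cohort(fixture_cohort, fixture_flags, top_k=5)
        top = s["top_drugs"][0]
        assert top["atc_level5"] == "B01AC06"
        assert top["n"] == 70
        assert top["pct"] == 18.0
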