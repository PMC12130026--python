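"""Statistics for the screening analysis.

Prevalence, crude odds ratios from 2x2 tables (Woolf log-normal confidence
intervals), the p < 0.25 bivariate screen, multivariable logistic regression
(adjusted odds ratios via maximum likelihood), the single-proportion sample
size formula, and demographic/drug summaries.

Display conventions: odds ratios to 2 decimal places, percentages to 1,
rounding half-up; interquartile ranges printed as "median (Q3-Q1)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, medication_count_category
from .comorbidity import comorbidity_category
from .drugs import load_catalog
from .engine import FlagTable

#: Significance level for adjusted-model reporting.
ALPHA = 0.05
#: Inclusion threshold of the bivariate screen feeding the adjusted model.
BIVARIATE_P = 0.25

#: Age bands used throughout the analysis (years).
AGE_BANDS = ["60-64", "65-69", "70-74", "75-79", "80-84", "85+"]

#: Reference levels of the adjusted model's dummy coding.
REFERENCE_LEVELS = {
    "sex": "female",
    "age_band": "60-64",
    "med_band": "low",
    "comorbidity": "none",
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def age_band(age_years: int) -> str:
    if age_years >= 85:
        return "85+"
    lo = 60 + 5 * ((age_years - 60) // 5)
    return f"{lo}-{lo + 4}"


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: a=exposed with outcome, b=exposed without,
    c=unexposed with outcome, d=unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("2x2 cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("2x2 table must contain at least one observation")


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # crude | adjusted

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the odds ratio")


@dataclass(frozen=True)
class LogisticModelResult:
    """Adjusted odds ratios per non-reference level of each covariate."""

    levels: dict[str, ORResult]          # "covariate=level" -> ORResult
    reference_levels: dict[str, str]
    converged: bool
    n_obs: int
    coefficients: dict[str, float]


class ConvergenceError(RuntimeError):
    """The likelihood maximisation failed or the data are separated."""


def prevalence(flag_table: FlagTable, n: Optional[int] = None) -> tuple[float, float]:
    """(proportion, percentage to 1 d.p.) of patients with at least one PIM."""
    n = flag_table.n_patients if n is None else n
    if n <= 0:
        raise ValueError("cohort size must be positive")
    k = len(flag_table.flagged_patients())
    prop = k / n
    return prop, round_half_up(100.0 * prop, 1)


def crude_or(t: TwoByTwoTable, continuity_correction: bool = False) -> ORResult:
    """Crude odds ratio (a*d)/(b*c) with Woolf log-normal 95% CI and a
    two-sided Wald p-value.

    Zero cells are rejected unless ``continuity_correction`` is set, in which
    case 0.5 is added to every cell (documented Haldane-Anscombe option).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise ValueError(
                "2x2 table has a zero cell; re-run with "
                "continuity_correction=True to add 0.5 to all cells"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z975 = stats.norm.ppf(0.975)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - z975 * se)
    ci_high = math.exp(log_or + z975 * se)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return ORResult(or_, ci_low, ci_high, p, method="crude")


def bivariate_screen(
    tables: dict[str, pd.DataFrame] | dict[str, np.ndarray],
    p_threshold: float = BIVARIATE_P,
) -> tuple[list[str], dict[str, float]]:
    """Select exposures whose k x 2 cross-tabulation against the outcome has
    Pearson chi-square p below ``p_threshold``.

    Falls back to Fisher's exact test (2 x 2 only) when any expected cell
    count is below 1.  Returns (selected names, p-value per exposure).
    """
    selected, pvalues = [], {}
    for name, table in tables.items():
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"exposure {name!r}: expected a k x 2 count table")
        chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
        if (expected < 1).any():
            if arr.shape != (2, 2):
                raise ValueError(
                    f"exposure {name!r}: expected cell below 1 in a k x 2 table; "
                    "collapse sparse levels before screening"
                )
            _, p = stats.fisher_exact(arr)
        pvalues[name] = float(p)
        if p < p_threshold:
            selected.append(name)
    return selected, pvalues


def patient_covariates(cohort: Cohort, flag_table: FlagTable) -> pd.DataFrame:
    """Per-patient analysis rows: PIM outcome plus the four study covariates."""
    flagged = flag_table.flagged_patients()
    rows = []
    for p in cohort:
        rows.append({
            "patient_id": p.patient_id,
            "pim": int(p.patient_id in flagged),
            "sex": p.sex,
            "age_band": age_band(p.age_years),
            "med_band": medication_count_category(p),
            "comorbidity": comorbidity_category(p.conditions),
        })
    return pd.DataFrame(rows)


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    level_order = {
        "sex": ["female", "male"],
        "age_band": AGE_BANDS,
        "med_band": ["low", "mid", "high"],
        "comorbidity": ["none", "comorbidity", "multimorbidity"],
    }
    cols, names = [np.ones(len(df))], ["intercept"]
    for cov in covariates:
        levels = level_order.get(cov) or sorted(df[cov].unique())
        ref = REFERENCE_LEVELS.get(cov, levels[0])
        for lv in levels:
            if lv == ref or lv not in set(df[cov]):
                continue
            cols.append((df[cov] == lv).to_numpy(dtype=float))
            names.append(f"{cov}={lv}")
    return np.column_stack(cols), names


def fit_multivariable_logistic(
    records: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age_band", "med_band", "comorbidity"),
    outcome: str = "pim",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticModelResult:
    """Maximum-likelihood logistic fit; adjusted OR = exp(coefficient) with
    Wald 95% CIs and p-values.

    Dummy coding is against the study reference levels (female, 60-64 years,
    1-4 medications, no comorbidity).  Non-convergence or separation raises
    :class:`ConvergenceError` rather than returning silent output.
    """
    import statsmodels.api as sm

    y = records[outcome].to_numpy(dtype=float)
    X, names = _design_matrix(records, covariates)
    for j, name in enumerate(names[1:], start=1):
        col = X[:, j].astype(bool)
        if y[col].sum() == 0 or (1 - y[col]).sum() == 0:
            raise ConvergenceError(
                f"level {name} has no events or no non-events (separation); "
                "collapse the level or drop the covariate"
            )
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
    except Exception as exc:  # PerfectSeparationError and friends
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    z975 = stats.norm.ppf(0.975)
    params, bse, pvals = fit.params, fit.bse, fit.pvalues
    levels = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        beta, se = params[j], bse[j]
        levels[name] = ORResult(
            odds_ratio=math.exp(beta),
            ci_low=math.exp(beta - z975 * se),
            ci_high=math.exp(beta + z975 * se),
            p_value=float(pvals[j]),
            method="adjusted",
        )
    return LogisticModelResult(
        levels=levels,
        reference_levels={c: REFERENCE_LEVELS.get(c, "") for c in covariates},
        converged=True,
        n_obs=len(records),
        coefficients=dict(zip(names, params)),
    )


def sample_size(p: float, d: float, z: float = 1.96, attrition: float = 0.0) -> int:
    """Single-proportion sample size n0 = z^2 p (1-p) / d^2, inflated by the
    anticipated attrition fraction (n0 * (1 + attrition)) and rounded up.

    The minimum returned size is 1.
    """
    if not (0 < p < 1):
        raise ValueError("expected prevalence p must lie in (0, 1)")
    if d <= 0:
        raise ValueError("precision d must be positive")
    if not (0 <= attrition < 1):
        raise ValueError("attrition fraction must lie in [0, 1)")
    n0 = (z ** 2) * p * (1 - p) / (d ** 2)
    return max(1, math.ceil(n0 * (1 + attrition)))


def summarize_cohort(cohort: Cohort, flag_table: Optional[FlagTable] = None,
                     top_k: int = 20) -> dict:
    """Demographics-style summary plus, when a screening result is supplied,
    the top inappropriately prescribed drugs by instance count."""
    ages = np.array([p.age_years for p in cohort])
    med_counts = np.array([len(p.medications) for p in cohort])
    n = len(cohort)

    def med_iqr(values: np.ndarray) -> str:
        med = round_half_up(float(np.median(values)))
        q1 = round_half_up(float(np.percentile(values, 25)))
        q3 = round_half_up(float(np.percentile(values, 75)))
        return f"{med:.0f} ({q3:.0f}-{q1:.0f})"

    sex_counts = pd.Series([p.sex for p in cohort]).value_counts().to_dict()
    band_counts = pd.Series([age_band(p.age_years) for p in cohort]) \
        .value_counts().reindex(AGE_BANDS, fill_value=0).to_dict()
    med_bands = pd.Series([medication_count_category(p) for p in cohort]) \
        .value_counts().reindex(["low", "mid", "high"], fill_value=0).to_dict()
    from .comorbidity import cci_score
    cci_bands = pd.Series([cci_score(p.conditions).band for p in cohort]) \
        .value_counts().reindex(["none", "mild", "moderate", "severe"], fill_value=0).to_dict()

    summary = {
        "n": n,
        "age_median_iqr": med_iqr(ages),
        "sex_counts": sex_counts,
        "sex_pct": {k: round_half_up(100 * v / n, 1) for k, v in sex_counts.items()},
        "age_band_counts": band_counts,
        "total_medications": int(med_counts.sum()),
        "medications_median_iqr": med_iqr(med_counts),
        "med_band_counts": med_bands,
        "cci_band_counts": cci_bands,
    }
    if flag_table is not None:
        catalog = load_catalog()
        from .engine import tally
        drug_counts = tally(flag_table, by="drug")
        total = int(len(flag_table))
        top = []
        for code, count in drug_counts.head(top_k).items():
            top.append({
                "atc_level5": code,
                "atc_level2": code[:3],
                "name": catalog.name_of(code),
                "n": int(count),
                "pct": round_half_up(100 * count / total, 0) if total else 0.0,
            })
        summary["total_pim_instances"] = total
        summary["top_drugs"] = top
        prop, pct = prevalence(flag_table, n)
        summary["pim_prevalence_pct"] = pct
    return summary
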