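"""Synthetic cohort generation.

The generator emulates the published cohort marginals — 55.3% male, the six
age bands, the 1-4/5-9/>=10 medication bands, hypertension and diabetes
prevalences of 49.6% and 33.8% — and attaches criterion-triggering
prescription constellations at configurable per-patient rates (defaulting to
the published per-criterion instance counts over 450 patients).  Covariates
are sampled independently; the joint correlation structure of the real
cohort was never reported and is not claimed.

For regression parameter recovery, PIM exposure is *planted*: drawn from a
logistic model on the four analysis covariates with configurable log-odds
(defaulting to the published adjusted odds ratios), with the intercept
calibrated so the marginal exposure prevalence matches the published 56.6%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, LabPanel, MedicationOrder, PatientRecord
from .recipes import TRIGGER_RECIPES, med
from . import reference_data as ref


class InfeasibleSpecError(ValueError):
    """The requested spec is internally contradictory."""


def _default_age_band_probs() -> dict[str, float]:
    return {b: k / ref.COHORT_N for b, k in ref.AGE_BAND_COUNTS.items()}


def _default_med_band_probs() -> dict[str, float]:
    return {b: k / ref.COHORT_N for b, k in ref.MED_BAND_COUNTS.items()}


def _default_condition_prevalences() -> dict[str, float]:
    # most prevalent comorbidities as published; the remainder chosen as
    # plausible hospital-cohort rates (documented in the methods note)
    return {
        "hypertension": ref.CONDITION_PREVALENCES["hypertension"],
        "diabetes_type2": ref.CONDITION_PREVALENCES["diabetes_type2"],
        "coronary_artery_disease": 0.20,
        "heart_failure": 0.10,
        "atrial_fibrillation": 0.08,
        "stroke": 0.08,
        "copd": 0.10,
        "cancer": 0.06,
        "renal_failure": 0.08,
        "recurrent_falls": 0.10,
        "dementia": 0.05,
        "peptic_ulcer_disease": 0.05,
        "osteoarthritis": 0.10,
        "allergy_pruritus": 0.10,
        "insomnia": 0.08,
        "depression": 0.06,
    }


def _default_trigger_rates() -> dict[str, float]:
    return {cid: k / ref.COHORT_N for cid, k in ref.CRITERION_COUNTS.items()}


def _default_planted_effects() -> dict[str, float]:
    return {f"{_COVARIATE_OF[k]}={_LEVEL_OF[k]}": math.log(v)
            for k, v in ref.PUBLISHED_ADJUSTED_OR.items()}


_COVARIATE_OF = {
    "sex_male": "sex", "age_65_69": "age_band", "age_70_74": "age_band",
    "age_75_79": "age_band", "age_80_84": "age_band", "age_85_plus": "age_band",
    "meds_mid": "med_band", "meds_high": "med_band",
    "comorbidity": "comorbidity", "multimorbidity": "comorbidity",
}
_LEVEL_OF = {
    "sex_male": "male", "age_65_69": "65-69", "age_70_74": "70-74",
    "age_75_79": "75-79", "age_80_84": "80-84", "age_85_plus": "85+",
    "meds_mid": "mid", "meds_high": "high",
    "comorbidity": "comorbidity", "multimorbidity": "multimorbidity",
}

#: Comorbidity-category marginals of the published cross-tabulation.
_COMORBIDITY_PROBS = {"none": 138 / 450, "comorbidity": 158 / 450,
                      "multimorbidity": 154 / 450}

#: Target marginal exposure prevalence for intercept calibration.
_TARGET_PREVALENCE = 0.566

_MED_BAND_RANGE = {"low": (1, 4), "mid": (5, 9), "high": (10, 14)}

_PAD_MEDS = [
    med("A11BA01", 1, days=30), med("A12AA04", 500, days=30),
    med("A11CC05", 20, unit="ug", days=30), med("B03BB01", 5, days=30),
    med("A11GA01", 500, days=30), med("A11HA02", 25, days=30),
    med("A12BA01", 600, days=30), med("A10AB01", 20, route="parenteral", days=30),
    med("N02BE01", 1000, days=10), med("B03AA07", 200, days=30),
    med("C10AA01", 20, days=60), med("A02BA03", 40, days=14),
]


@dataclass(frozen=True)
class CohortSpec:
    n: int = ref.COHORT_N
    seed: int = 0
    sex_p_male: float = ref.SEX_COUNTS["male"] / ref.COHORT_N
    age_band_probs: dict = field(default_factory=_default_age_band_probs)
    med_band_probs: dict = field(default_factory=_default_med_band_probs)
    condition_prevalences: dict = field(default_factory=_default_condition_prevalences)
    criterion_trigger_rates: dict = field(default_factory=_default_trigger_rates)
    planted_effects: dict = field(default_factory=_default_planted_effects)
    intercept: Optional[float] = None   # None -> calibrated to 56.6% marginal

    def validate(self) -> None:
        if self.n <= 0:
            raise InfeasibleSpecError("cohort size n must be positive")
        if not (0 <= self.sex_p_male <= 1):
            raise InfeasibleSpecError("sex_p_male must lie in [0, 1]")
        for name, probs in (("age_band_probs", self.age_band_probs),
                            ("med_band_probs", self.med_band_probs)):
            if any(p < 0 for p in probs.values()):
                raise InfeasibleSpecError(f"{name} must be non-negative")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise InfeasibleSpecError(f"{name} must sum to 1")
        for cond, p in self.condition_prevalences.items():
            if not (0 <= p <= 1):
                raise InfeasibleSpecError(f"prevalence of {cond} must lie in [0, 1]")
        for cid, rate in self.criterion_trigger_rates.items():
            if cid not in TRIGGER_RECIPES:
                raise InfeasibleSpecError(f"unknown criterion id {cid!r}")
            if not (0 <= rate <= 1):
                raise InfeasibleSpecError(f"trigger rate of {cid} must lie in [0, 1]")
            if rate > 0:
                recipe = TRIGGER_RECIPES[cid]
                for cond in recipe.conditions:
                    if self.condition_prevalences.get(cond, None) == 0.0:
                        raise InfeasibleSpecError(
                            f"criterion {cid} has trigger rate {rate} but its "
                            f"required condition {cond!r} has prevalence 0"
                        )


def calibrate_intercept(spec: CohortSpec) -> float:
    """Intercept giving the target 56.6% marginal exposure prevalence under
    the spec's (independent) covariate distribution.  Closed-form enumeration
    over the 108 covariate cells; no randomness."""
    levels = {
        "sex": [("female", 1 - spec.sex_p_male), ("male", spec.sex_p_male)],
        "age_band": list(spec.age_band_probs.items()),
        "med_band": list(spec.med_band_probs.items()),
        "comorbidity": list(_COMORBIDITY_PROBS.items()),
    }
    cells: list[tuple[float, float]] = [(0.0, 1.0)]   # (linear predictor, prob)
    for cov, lvls in levels.items():
        cells = [
            (xb + spec.planted_effects.get(f"{cov}={lv}", 0.0), w * p)
            for xb, w in cells for lv, p in lvls
        ]

    def marginal(b0: float) -> float:
        return sum(w / (1 + math.exp(-(b0 + xb))) for xb, w in cells)

    return float(brentq(lambda b: marginal(b) - _TARGET_PREVALENCE, -20, 20))


def simulate_analysis_frame(spec: CohortSpec,
                            rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Fast path for regression studies: per-patient covariates plus a PIM
    exposure planted from the logistic model the spec implies."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n
    sex = np.where(rng.random(n) < spec.sex_p_male, "male", "female")
    bands = list(spec.age_band_probs)
    age_band = rng.choice(bands, size=n, p=[spec.age_band_probs[b] for b in bands])
    mbands = list(spec.med_band_probs)
    med_band = rng.choice(mbands, size=n, p=[spec.med_band_probs[b] for b in mbands])
    cbands = list(_COMORBIDITY_PROBS)
    comorbidity = rng.choice(cbands, size=n, p=[_COMORBIDITY_PROBS[b] for b in cbands])
    df = pd.DataFrame({"sex": sex, "age_band": age_band,
                       "med_band": med_band, "comorbidity": comorbidity})
    df["pim"] = plant_effects(df, spec, rng)
    return df


def plant_effects(covariates: pd.DataFrame, spec: CohortSpec,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw PIM exposure (0/1) from the logistic model implied by the spec's
    planted log-odds for each covariate row."""
    rng = rng or np.random.default_rng(spec.seed)
    b0 = spec.intercept if spec.intercept is not None else calibrate_intercept(spec)
    xb = np.full(len(covariates), b0)
    for term, beta in spec.planted_effects.items():
        cov, level = term.split("=", 1)
        xb += beta * (covariates[cov] == level).to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-xb))
    return (rng.random(len(covariates)) < p).astype(int)


def generate(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort of validated patient records.

    Covariates are sampled from the spec marginals, conditions from their
    prevalences, and criterion-triggering prescription constellations are
    attached by Bernoulli draws at the spec trigger rates (skipped when the
    patient's sex or age is incompatible with the recipe).  Laboratory values
    attached by a recipe sit just past the rule threshold so triggers are
    unambiguous.  Identical specs yield byte-identical serialized cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bands = list(spec.age_band_probs)
    mbands = list(spec.med_band_probs)
    trigger_items = sorted(spec.criterion_trigger_rates.items())
    # trigger recipes attach their required conditions, inflating condition
    # prevalence; deflate the base sampling probability so the realized
    # marginal converges to the spec prevalence
    induced: dict[str, float] = {}
    for cid, rate in trigger_items:
        for cond in TRIGGER_RECIPES[cid].conditions:
            induced[cond] = 1 - (1 - induced.get(cond, 0.0)) * (1 - rate)
    base_prev = {}
    for cond, p in spec.condition_prevalences.items():
        q = induced.get(cond, 0.0)
        base_prev[cond] = max(0.0, (p - q) / (1 - q)) if q < 1 else 0.0
    patients = []
    for i in range(spec.n):
        sex = "male" if rng.random() < spec.sex_p_male else "female"
        band = rng.choice(bands, p=[spec.age_band_probs[b] for b in bands])
        if band == "85+":
            age = 85 + int(rng.integers(0, 10))
        else:
            lo = int(band.split("-")[0])
            age = lo + int(rng.integers(0, 5))
        conditions = {
            cond for cond, p in sorted(base_prev.items()) if rng.random() < p
        }
        meds: list[MedicationOrder] = []
        labs: dict = {}
        for cid, rate in trigger_items:
            if rng.random() >= rate:
                continue
            recipe = TRIGGER_RECIPES[cid]
            if recipe.sex != sex and recipe.criterion_id in ("J5", "J6", "J7", "J8", "C15"):
                continue
            if recipe.age > age and recipe.criterion_id == "B16":
                continue
            if any(m.atc_code in {x.atc_code for x in meds} for m in recipe.meds):
                continue
            meds.extend(recipe.meds)
            conditions |= recipe.conditions
            labs.update(recipe.labs)
        med_band = rng.choice(mbands, p=[spec.med_band_probs[b] for b in mbands])
        lo, hi = _MED_BAND_RANGE[med_band]
        target = int(rng.integers(lo, hi + 1))
        have = {m.atc_code for m in meds}
        for candidate in _PAD_MEDS:
            if len(meds) >= target:
                break
            if candidate.atc_code not in have:
                meds.append(candidate)
                have.add(candidate.atc_code)
        if not meds:
            meds.append(_PAD_MEDS[0])
        patients.append(PatientRecord(
            patient_id=f"S{i + 1:05d}", age_years=age, sex=sex,
            conditions=frozenset(conditions), labs=LabPanel(**labs),
            medications=tuple(meds),
        ))
    return Cohort(patients=tuple(patients), source="synthetic", seed=spec.seed)
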