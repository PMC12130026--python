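"""Published reference tallies of the observational cohort this package
reconstructs.

These tables are *inputs* to the analysis: the cohort marginals drive the
synthetic generator's defaults, the per-criterion instance counts and drug
attributions define the deterministic reference fixture, and the published
cross-tabulations feed the odds-ratio stage directly.  Patient-level data
were never deposited, so the fixture realises one valid patient-level
arrangement consistent with these margins.
"""

from __future__ import annotations

COHORT_N = 450

# -- demographic marginals (counts) ---------------------------------------
SEX_COUNTS = {"male": 249, "female": 201}

AGE_BAND_COUNTS = {
    "60-64": 114, "65-69": 135, "70-74": 95,
    "75-79": 35, "80-84": 33, "85+": 38,
}

#: Medication-count bands low (1-4), mid (5-9), high (>=10).  The published
#: band percentages are transposed relative to these counts; the counts sum
#: to the cohort size and are taken as authoritative.
MED_BAND_COUNTS = {"low": 91, "mid": 309, "high": 50}

CCI_BAND_COUNTS = {"mild": 95, "moderate": 261, "severe": 94}

#: Most prevalent comorbidities (proportion of cohort).
CONDITION_PREVALENCES = {"hypertension": 0.496, "diabetes_type2": 0.338}

# -- screening outcome ----------------------------------------------------
TOTAL_PIM_INSTANCES = 388
FLAGGED_PATIENTS = 255

#: Patients with exactly 1..5 PIMs (sums to 255; instances sum to 388).
PIMS_PER_PATIENT = {1: 163, 2: 62, 3: 22, 4: 5, 5: 3}

#: Non-zero per-criterion instance counts (all other criteria scored 0).
CRITERION_COUNTS = {
    "A1": 3, "A3": 3,
    "B2": 2, "B4": 2, "B5": 23, "B6": 1, "B7": 12, "B8": 9, "B13": 1,
    "B15": 6, "B16": 1, "B17": 1, "B18": 2, "B19": 4, "B21": 7,
    "C1": 5, "C2": 4, "C3": 4, "C4": 2, "C5": 13, "C10": 3, "C11": 3,
    "C12": 1, "C14": 2, "C16": 15,
    "D7": 4, "D8": 7, "D9": 2, "D10": 4, "D12": 2, "D13": 7, "D14": 1,
    "D24": 44,
    "E4": 39, "E6": 1,
    "F2": 5, "F6": 3,
    "G1": 1, "G2": 29,
    "H2": 1,
    "I5": 1, "I8": 5,
    "J1": 12, "J2": 6, "J4": 1, "J8": 1, "J9": 2,
    "K1": 6, "K2": 5, "K3": 27, "K5": 7, "K6": 2, "K7": 1,
    "L1": 6, "L2": 16, "L5": 8,
    "M1": 3,
}

#: Per-system instance sums implied by the criterion counts.
SYSTEM_COUNTS = {
    "indication": 6,
    "cardiovascular": 71,
    "coagulation": 52,
    "central_nervous_system": 71,
    "renal": 40,
    "gastrointestinal": 8,
    "respiratory": 30,
    "musculoskeletal": 1,
    "urogenital": 6,
    "endocrine": 22,
    "falls_risk": 48,
    "analgesic": 30,
    "anticholinergic_burden": 3,
}

#: Leading drugs among the published top-20 attribution (instances).  The
#: top rows are reproduced exactly by the reference fixture; lower rows are
#: not jointly consistent with the per-criterion counts under any
#: attribution and are treated as descriptive.
TOP_DRUG_COUNTS = {
    "B01AC06": 70,   # acetylsalicylic acid (18% of 388)
    "D04AA16": 44,   # pheniramine (11%)
    "H02AB09": 28,   # hydrocortisone (7%)
    "C02DB02": 22,   # hydralazine (6%)
    "N02AX02": 23,   # tramadol (6%)
}

# -- published exposure x PIM cross-tabulations (a, b, c, d) --------------
#: a = exposed with PIM, b = exposed without, c = reference with, d = without.
TABLE_2X2 = {
    "sex_male": (145, 104, 110, 91),
    "age_65_69": (77, 58, 63, 51),
    "age_70_74": (55, 40, 63, 51),
    "age_75_79": (22, 13, 63, 51),
    "age_80_84": (21, 12, 63, 51),
    "age_85_plus": (17, 21, 63, 51),
    "meds_mid": (184, 125, 30, 61),
    "meds_high": (41, 9, 30, 61),
    "comorbidity": (106, 52, 53, 85),
    "multimorbidity": (96, 58, 53, 85),
}

#: Published crude odds ratios for the rows above (point estimates).
PUBLISHED_CRUDE_OR = {
    "sex_male": 1.15,
    "meds_mid": 2.99,
    "meds_high": 9.26,
    "comorbidity": 3.27,
    "multimorbidity": 2.65,
}

#: Published adjusted odds ratios (multivariable model).
PUBLISHED_ADJUSTED_OR = {
    "sex_male": 1.31,
    "age_65_69": 1.35,
    "age_70_74": 1.38,
    "age_75_79": 1.76,
    "age_80_84": 1.54,
    "age_85_plus": 0.77,
    "meds_mid": 2.89,
    "meds_high": 8.42,
    "comorbidity": 3.12,
    "multimorbidity": 2.11,
}

#: Full k x 2 cross-tabulations for the bivariate screen
#: (rows = exposure levels with the reference level first; cols = PIM yes/no).
KX2_TABLES = {
    "sex": [[110, 91], [145, 104]],
    "age_band": [[63, 51], [77, 58], [55, 40], [22, 13], [21, 12], [17, 21]],
    "med_band": [[30, 61], [184, 125], [41, 9]],
    "comorbidity": [[53, 85], [106, 52], [96, 58]],
}

# -- sample-size calculation inputs ---------------------------------------
SAMPLE_SIZE_INPUTS = {"p": 0.64, "d": 0.05, "z": 1.96, "attrition": 0.20}
REQUIRED_SAMPLE = 425
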