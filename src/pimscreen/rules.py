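"""The 133 STOPP v3 criterion predicates.

Conventions shared by every rule:

* duration thresholds read calendar-literally from ``duration_days``:
  "> 3 months" = > 90 days, ">= 4 weeks" = >= 28, ">= 2 weeks" = >= 14,
  "> 8 weeks" = > 56, "> 12 weeks" = > 84, "> 6 months" = > 180, and
  "long-term" with no stated horizon = > 90 days;
* "first-line" / "monotherapy" clauses are decided from the absence of the
  alternative drug class on the current medication list (prescription
  sequence history is not modelled — a documented limitation);
* duplicate-class (A3) and anticholinergic-burden (M1) rules consider
  regular orders only; every other rule considers any order;
* a missing laboratory value needed by a fired drug clause yields
  ``NotEvaluable`` rather than false.

The renal NSAID rule (E4) includes low-dose aspirin — pharmacologically an
NSAID with the same renal prostaglandin effect — while the anti-inflammatory
duplicate/gastro/musculoskeletal NSAID rules use the ``nsaid`` tag, which
excludes the antiplatelet aspirin code.
"""

from __future__ import annotations

from typing import Optional

from .drugs import ANTIHYPERTENSIVE_TAGS
from .engine import CriterionDefinition, NotEvaluable, PatientView
from .vocab import CVD_CONDITIONS, SYSTEM_GROUPS

CRITERIA: dict[str, CriterionDefinition] = {}

ANTICOAG = ("vitamin_k_antagonist", "direct_thrombin_inhibitor", "factor_xa_inhibitor")

#: QTc-prolonging only above a dose threshold (mg/day).
QT_DOSE_CONDITIONAL = {"N06AB04": 20.0, "N06AB10": 10.0}

#: Antipsychotics tolerated in parkinsonism / Lewy-body dementia.
PARKINSON_SAFE_ANTIPSYCHOTICS = {"N05AH02", "N05AH04"}  # clozapine, quetiapine

#: Phenothiazines with an accepted non-antipsychotic indication.
PHENOTHIAZINE_EXCEPTIONS = {"N05AB04"}  # prochlorperazine (antiemetic)

#: Full therapeutic daily dose (mg) per PPI code; default 20 mg.
PPI_FULL_DOSE = {"A02BC01": 20.0}

#: Elemental-iron-equivalent daily dose limit (mg of salt) per oral iron code.
IRON_DOSE_LIMITS = {"B03AA07": 600.0}

#: Well-defined treatment durations (days) for the beyond-duration rule (A2).
RECOMMENDED_MAX_DAYS = {"J01CA04": 14, "J01FA09": 14, "J01MA02": 14}

#: Upper reference limit for TSH (mU/L): above this is "elevated".
TSH_UPPER_NORMAL = 4.5


def rule(criterion_id: str, summary: str):
    """Register a predicate under its criterion id."""
    section = criterion_id[0]
    system = SYSTEM_GROUPS[section]

    def decorate(fn):
        if criterion_id in CRITERIA:
            raise ValueError(f"duplicate criterion {criterion_id}")
        CRITERIA[criterion_id] = CriterionDefinition(
            criterion_id=criterion_id,
            system_group=system,
            summary=summary,
            predicate=fn,
        )
        return fn

    return decorate


def _each(meds) -> list[tuple]:
    return [(m,) for m in meds]


def _pairs(subjects, partners) -> list[tuple]:
    """One flag per subject, paired with the first partner drug."""
    if not subjects or not partners:
        return []
    return [(s, partners[0]) for s in subjects if s is not partners[0]]


def _lab_gate(pv: PatientView, subjects, lab_checks, condition_alt: bool = False):
    """Shared tri-state logic for lab-threshold rules.

    ``lab_checks``: list of (lab_name, predicate).  Triggers when any check
    passes; NotEvaluable when the drug clause is satisfied, no alternative
    condition applies, and every needed lab is missing.
    """
    if not subjects:
        return []
    if condition_alt:
        return _each(subjects)
    values = [(name, pv.lab(name)) for name, _ in lab_checks]
    if all(v is None for _, v in values):
        return NotEvaluable(*[name for name, _ in lab_checks])
    for (name, check), (_, v) in zip(lab_checks, values):
        if v is not None and check(v):
            return _each(subjects)
    return []


# =========================================================================
# Section A — indication of medication
# =========================================================================

@rule("A1", "drug prescribed without an evidence-based clinical indication")
def _a1(pv):
    return _each([m for m in pv.meds() if m.indication_code == "no_indication"])


@rule("A2", "drug continued beyond a well-defined recommended duration")
def _a2(pv):
    out = []
    for m in pv.meds():
        limit = RECOMMENDED_MAX_DAYS.get(m.atc_code)
        if limit is not None and m.duration_days > limit:
            out.append((m,))
    return out


@rule("A3", "duplicate drug-class prescription for regular use")
def _a3(pv):
    # classes named by the rule: NSAIDs, SSRIs, loop diuretics, ACE
    # inhibitors, anticoagulants, antipsychotics, opioid analgesics
    classes: list[tuple[str, ...]] = [
        ("nsaid",), ("ssri",), ("loop_diuretic",), ("ace_inhibitor",),
        ANTICOAG, ("antipsychotic",), ("opioid",),
    ]
    out = []
    for tags in classes:
        members = pv.meds(*tags, regular=True)
        codes = sorted({m.atc_code for m in members})
        if len(codes) >= 2:
            ordered = []
            for c in codes:
                ordered.append(next(m for m in members if m.atc_code == c))
            out.append(tuple(ordered))
    return out


# =========================================================================
# Section B — cardiovascular system
# =========================================================================

@rule("B1", "digoxin for heart failure with preserved systolic function")
def _b1(pv):
    if pv.has("heart_failure_preserved_ef"):
        return _each(pv.meds("digoxin"))
    return []


@rule("B2", "verapamil or diltiazem with NYHA class III-IV heart failure")
def _b2(pv):
    if pv.has("heart_failure_nyha_3_4"):
        return _each(pv.meds("verapamil_diltiazem"))
    return []


@rule("B3", "beta-blocker combined with verapamil or diltiazem")
def _b3(pv):
    return _pairs(pv.meds("beta_blocker"), pv.meds("verapamil_diltiazem"))


@rule("B4", "rate-limiting drug with bradycardia or heart block")
def _b4(pv):
    subjects = pv.meds("beta_blocker", "verapamil_diltiazem", "digoxin")
    if not subjects:
        return []
    if pv.has("bradycardia", "heart_block"):
        return _each(subjects)
    hr = pv.lab("heart_rate")
    if hr is None:
        return NotEvaluable("heart_rate")
    return _each(subjects) if hr < 50 else []


@rule("B5", "beta-blocker as monotherapy for uncomplicated hypertension")
def _b5(pv):
    if not pv.has("hypertension"):
        return []
    if pv.has("angina", "aortic_aneurysm", "heart_failure",
              "heart_failure_preserved_ef", "heart_failure_nyha_3_4",
              "atrial_fibrillation", "mi_history"):
        return []
    subjects = pv.meds("beta_blocker")
    if not subjects:
        return []
    others = ANTIHYPERTENSIVE_TAGS - {"beta_blocker"}
    if pv.on(*others):
        return []
    return _each(subjects)


@rule("B6", "amiodarone as first-line therapy for supraventricular tachyarrhythmia")
def _b6(pv):
    if not pv.has("supraventricular_tachyarrhythmia"):
        return []
    if pv.on("beta_blocker", "digoxin", "verapamil_diltiazem"):
        return []
    return _each(pv.meds("amiodarone"))


@rule("B7", "loop diuretic as first-line treatment for hypertension")
def _b7(pv):
    if not pv.has("hypertension"):
        return []
    if pv.has("heart_failure", "heart_failure_preserved_ef", "heart_failure_nyha_3_4"):
        return []
    subjects = pv.meds("loop_diuretic")
    if not subjects:
        return []
    others = ANTIHYPERTENSIVE_TAGS - {"loop_diuretic"}
    if pv.on(*others):
        return []
    return _each(subjects)


@rule("B8", "loop diuretic for dependent ankle edema without cardiac, hepatic or renal cause")
def _b8(pv):
    if not pv.has("dependent_ankle_edema"):
        return []
    if pv.has("heart_failure", "heart_failure_preserved_ef", "heart_failure_nyha_3_4",
              "liver_disease_mild", "liver_disease_severe",
              "nephrotic_syndrome", "renal_failure"):
        return []
    return _each(pv.meds("loop_diuretic"))


@rule("B9", "thiazide with hypokalemia, hyponatremia, hypercalcemia or gout history")
def _b9(pv):
    subjects = pv.meds("thiazide")
    if not subjects:
        return []
    if pv.has("gout"):
        return _each(subjects)
    return _lab_gate(pv, subjects, [
        ("serum_k", lambda v: v < 3.0),
        ("serum_na", lambda v: v < 130.0),
        ("corrected_ca", lambda v: v > 2.65),
    ])


@rule("B10", "loop diuretic for hypertension with urinary incontinence")
def _b10(pv):
    if pv.has("hypertension") and pv.has("urinary_incontinence"):
        return _each(pv.meds("loop_diuretic"))
    return []


@rule("B11", "centrally acting antihypertensive without intolerance of other classes")
def _b11(pv):
    if pv.has("antihypertensive_intolerance"):
        return []
    return _each(pv.meds("central_antihypertensive"))


@rule("B12", "ACE inhibitor or ARB with hyperkalemia")
def _b12(pv):
    return _lab_gate(pv, pv.meds("ace_inhibitor", "arb"),
                     [("serum_k", lambda v: v > 5.5)])


@rule("B13", "aldosterone antagonist plus potassium-conserving drug without potassium monitoring")
def _b13(pv):
    subjects = pv.meds("aldosterone_antagonist")
    partners = pv.meds("ace_inhibitor", "arb")
    if not subjects or not partners:
        return []
    # absence of a serum potassium value IS the absent-monitoring trigger
    if pv.lab("serum_k") is not None:
        return []
    return _pairs(subjects, partners)


@rule("B14", "PDE5 inhibitor in severe heart failure with hypotension or with nitrate therapy")
def _b14(pv):
    subjects = pv.meds("pde5_inhibitor")
    if not subjects:
        return []
    nitrates = pv.meds("nitrate")
    if nitrates:
        return _pairs(subjects, nitrates)
    sbp = pv.lab("systolic_bp")
    if sbp is None:
        return NotEvaluable("systolic_bp")
    return _each(subjects) if sbp < 90 else []


@rule("B15", "QTc-prolonging drug with known QTc prolongation")
def _b15(pv):
    subjects = list(pv.meds("qtc_prolonging"))
    for m in pv.meds():
        threshold = QT_DOSE_CONDITIONAL.get(m.atc_code)
        if threshold is not None and m.dose_mg > threshold and m not in subjects:
            subjects.append(m)
    if not subjects:
        return []
    qtc = pv.lab("qtc_ms")
    if qtc is None:
        return NotEvaluable("qtc_ms")
    limit = 450.0 if pv.sex == "male" else 470.0
    return _each(subjects) if qtc > limit else []


@rule("B16", "statin for primary prevention at age >= 85 with limited life expectancy")
def _b16(pv):
    if pv.age < 85 or not pv.has("frailty_limited_life_expectancy"):
        return []
    if pv.has(*CVD_CONDITIONS):
        return []
    return _each(pv.meds("statin"))


@rule("B17", "long-term systemic NSAID with established vascular disease")
def _b17(pv):
    if not pv.has(*CVD_CONDITIONS):
        return []
    return _each(pv.meds("nsaid", route_not=("topical",), min_days=91))


@rule("B18", "long-term antipsychotic with established vascular disease")
def _b18(pv):
    if not pv.has(*CVD_CONDITIONS):
        return []
    return _each(pv.meds("antipsychotic", min_days=91))


@rule("B19", "NSAID or systemic corticosteroid with heart failure on loop diuretic")
def _b19(pv):
    if not pv.has("heart_failure", "heart_failure_preserved_ef", "heart_failure_nyha_3_4"):
        return []
    if not pv.on("loop_diuretic"):
        return []
    return _each(pv.meds("nsaid") + pv.meds("systemic_corticosteroid"))


@rule("B20", "non-RAS antihypertensive in severe symptomatic aortic stenosis")
def _b20(pv):
    if not pv.has("severe_symptomatic_aortic_stenosis"):
        return []
    tags = ANTIHYPERTENSIVE_TAGS - {"ace_inhibitor", "arb"}
    return _each(pv.meds(*tags))


@rule("B21", "digoxin as first-line long-term rate control in atrial fibrillation")
def _b21(pv):
    if not pv.has("atrial_fibrillation"):
        return []
    if pv.on("beta_blocker"):
        return []
    return _each(pv.meds("digoxin", min_days=91))


# =========================================================================
# Section C — coagulation system
# =========================================================================

@rule("C1", "long-term aspirin above 100 mg per day")
def _c1(pv):
    return _each([
        m for m in pv.meds("aspirin", min_days=91) if m.dose_mg > 100.0
    ])


@rule("C2", "antithrombotic with significant bleeding risk")
def _c2(pv):
    if not pv.has("uncontrolled_severe_hypertension", "bleeding_diathesis",
                  "recent_bleeding"):
        return []
    return _each(pv.meds("antiplatelet", *ANTICOAG))


@rule("C3", "aspirin plus clopidogrel beyond 4 weeks for secondary stroke prevention")
def _c3(pv):
    if not pv.has("stroke"):
        return []
    if pv.has("coronary_stent_recent", "acute_coronary_syndrome",
              "carotid_stenosis_symptomatic"):
        return []
    aspirin = pv.meds("aspirin", min_days=29)
    clopidogrel = [m for m in pv.meds("antiplatelet", min_days=29)
                   if m.atc_code == "B01AC04"]
    return _pairs(aspirin, clopidogrel)


@rule("C4", "antiplatelet plus anticoagulant in chronic atrial fibrillation")
def _c4(pv):
    if not pv.has("atrial_fibrillation"):
        return []
    if pv.has("coronary_stent_recent", "coronary_stenosis_high_grade"):
        return []
    return _pairs(pv.meds("antiplatelet"), pv.meds(*ANTICOAG))


@rule("C5", "antiplatelet plus anticoagulant in stable arterial disease without anticoagulant indication")
def _c5(pv):
    if not pv.has("coronary_artery_disease", "mi_history", "stroke",
                  "cerebrovascular_disease", "peripheral_vascular_disease"):
        return []
    if pv.has("atrial_fibrillation", "vte_history", "metallic_heart_valve",
              "mitral_stenosis"):
        return []
    return _pairs(pv.meds("antiplatelet"), pv.meds(*ANTICOAG))


@rule("C6", "ticlopidine in any circumstances")
def _c6(pv):
    return _each(pv.meds("ticlopidine"))


@rule("C7", "antiplatelet instead of anticoagulant for stroke prevention in atrial fibrillation")
def _c7(pv):
    if not pv.has("atrial_fibrillation"):
        return []
    if pv.on(*ANTICOAG):
        return []
    return _each(pv.meds("antiplatelet"))


@rule("C8", "anticoagulant beyond 6 months for a first unprovoked deep venous thrombosis")
def _c8(pv):
    if not pv.has("first_dvt") or pv.has("persistent_vte_risk"):
        return []
    return _each(pv.meds(*ANTICOAG, min_days=181))


@rule("C9", "anticoagulant beyond 6 months for a first unprovoked pulmonary embolus")
def _c9(pv):
    if not pv.has("first_pe") or pv.has("persistent_vte_risk"):
        return []
    return _each(pv.meds(*ANTICOAG, min_days=181))


@rule("C10", "NSAID combined with an anticoagulant")
def _c10(pv):
    return _pairs(pv.meds("nsaid"), pv.meds(*ANTICOAG))


@rule("C11", "vitamin K antagonist as first-line anticoagulant for atrial fibrillation")
def _c11(pv):
    if not pv.has("atrial_fibrillation"):
        return []
    if pv.has("metallic_heart_valve", "mitral_stenosis"):
        return []
    egfr = pv.lab("egfr")
    if egfr is not None and egfr < 15:
        return []
    if pv.on("direct_thrombin_inhibitor", "factor_xa_inhibitor"):
        return []
    return _each(pv.meds("vitamin_k_antagonist"))


@rule("C12", "SSRI plus anticoagulant with previous major hemorrhage")
def _c12(pv):
    if not pv.has("bleeding_history_major"):
        return []
    return _pairs(pv.meds("ssri"), pv.meds(*ANTICOAG))


@rule("C13", "direct thrombin inhibitor with verapamil or diltiazem")
def _c13(pv):
    return _pairs(pv.meds("direct_thrombin_inhibitor"), pv.meds("verapamil_diltiazem"))


@rule("C14", "direct oral anticoagulant with a P-glycoprotein inhibitor")
def _c14(pv):
    doacs = pv.meds("direct_thrombin_inhibitor", "factor_xa_inhibitor")
    return _pairs(doacs, pv.meds("p_gp_inhibitor"))


@rule("C15", "systemic estrogen with previous venous thromboembolism")
def _c15(pv):
    if pv.has("vte_history"):
        return _each(pv.meds("systemic_estrogen"))
    return []


@rule("C16", "aspirin for primary prevention of cardiovascular disease")
def _c16(pv):
    if pv.has(*CVD_CONDITIONS) or pv.has("atrial_fibrillation",
                                         "carotid_stenosis_symptomatic"):
        return []
    return _each(pv.meds("aspirin"))


# =========================================================================
# Section D — central nervous system
# =========================================================================

@rule("D1", "tricyclic antidepressant with an anticholinergic-sensitive condition")
def _d1(pv):
    if not pv.has("dementia", "narrow_angle_glaucoma", "heart_block",
                  "bph_luts", "chronic_constipation", "recurrent_falls",
                  "urinary_retention_history"):
        return []
    return _each(pv.meds("tca"))


@rule("D2", "tricyclic antidepressant as first-line treatment for major depression")
def _d2(pv):
    if not pv.has("depression"):
        return []
    if pv.on("ssri", "snri"):
        return []
    return _each(pv.meds("tca"))


@rule("D3", "SNRI with severe hypertension")
def _d3(pv):
    return _lab_gate(pv, pv.meds("snri"), [
        ("systolic_bp", lambda v: v > 180.0),
        ("diastolic_bp", lambda v: v > 105.0),
    ])


@rule("D4", "strongly anticholinergic antipsychotic with prostatic symptoms or urinary retention")
def _d4(pv):
    if not pv.has("bph_luts", "urinary_retention_history"):
        return []
    return _each(pv.meds("antipsychotic_anticholinergic"))


@rule("D5", "antipsychotic for BPSD beyond 3 months without review")
def _d5(pv):
    if not pv.has("bpsd"):
        return []
    return _each(pv.meds("antipsychotic", min_days=91))


@rule("D6", "SSRI with significant hyponatremia")
def _d6(pv):
    return _lab_gate(pv, pv.meds("ssri"), [("serum_na", lambda v: v < 130.0)])


@rule("D7", "SSRI with current or recent significant bleeding")
def _d7(pv):
    if pv.has("recent_bleeding"):
        return _each(pv.meds("ssri"))
    return []


@rule("D8", "benzodiazepine for 4 weeks or longer")
def _d8(pv):
    return _each(pv.meds("benzodiazepine", min_days=28))


@rule("D9", "benzodiazepine for agitated behavior or noncognitive symptoms of dementia")
def _d9(pv):
    if pv.has("bpsd"):
        return _each(pv.meds("benzodiazepine"))
    return []


@rule("D10", "benzodiazepine for insomnia for 2 weeks or longer")
def _d10(pv):
    if not pv.has("insomnia"):
        return []
    return _each(pv.meds("benzodiazepine", min_days=14))


@rule("D11", "Z-drug for insomnia for 2 weeks or longer")
def _d11(pv):
    if not pv.has("insomnia"):
        return []
    return _each(pv.meds("z_drug", min_days=14))


@rule("D12", "antipsychotic other than clozapine or quetiapine in parkinsonism or Lewy-body dementia")
def _d12(pv):
    if not pv.has("parkinsonism", "lewy_body_dementia"):
        return []
    return _each(pv.meds("antipsychotic",
                         exclude_codes=tuple(PARKINSON_SAFE_ANTIPSYCHOTICS)))


@rule("D13", "anticholinergic to treat extrapyramidal side effects of antipsychotics")
def _d13(pv):
    subjects = pv.meds("antiparkinson_anticholinergic")
    if not subjects:
        return []
    if pv.on("antipsychotic") or pv.has("drug_induced_parkinsonism"):
        return _each(subjects)
    return []


@rule("D14", "potent anticholinergic in delirium or dementia")
def _d14(pv):
    if not pv.has("delirium", "dementia"):
        return []
    return _each(pv.meds("anticholinergic"))


@rule("D15", "neuroleptic for noncognitive symptoms of dementia beyond 12 weeks")
def _d15(pv):
    if not pv.has("bpsd") or pv.has("bpsd_severe_refractory"):
        return []
    return _each(pv.meds("antipsychotic", min_days=85))


@rule("D16", "neuroleptic antipsychotic as hypnotic")
def _d16(pv):
    if not pv.has("insomnia"):
        return []
    if pv.has("psychosis", "bpsd"):
        return []
    return _each(pv.meds("antipsychotic"))


@rule("D17", "acetylcholinesterase inhibitor with bradycardia, heart block or unexplained syncope")
def _d17(pv):
    subjects = pv.meds("acetylcholinesterase_inhibitor")
    if not subjects:
        return []
    if pv.has("bradycardia", "heart_block", "syncope_history"):
        return _each(subjects)
    hr = pv.lab("heart_rate")
    if hr is None:
        return NotEvaluable("heart_rate")
    return _each(subjects) if hr < 60 else []


@rule("D18", "acetylcholinesterase inhibitor with a heart-rate-lowering drug")
def _d18(pv):
    return _pairs(pv.meds("acetylcholinesterase_inhibitor"),
                  pv.meds("beta_blocker", "digoxin", "verapamil_diltiazem"))


@rule("D19", "memantine with current or previous seizure disorder")
def _d19(pv):
    if pv.has("epilepsy"):
        return _each(pv.meds("memantine"))
    return []


@rule("D20", "nootropic in dementia")
def _d20(pv):
    if pv.has("dementia", "lewy_body_dementia"):
        return _each(pv.meds("nootropic"))
    return []


@rule("D21", "phenothiazine as first-line treatment for psychosis or noncognitive symptoms of dementia")
def _d21(pv):
    if not pv.has("psychosis", "bpsd"):
        return []
    subjects = pv.meds("phenothiazine",
                       exclude_codes=tuple(PHENOTHIAZINE_EXCEPTIONS))
    if not subjects:
        return []
    other_aps = [m for m in pv.meds("antipsychotic") if m not in subjects]
    if other_aps:
        return []
    return _each(subjects)


@rule("D22", "levodopa or dopamine agonist for benign essential tremor")
def _d22(pv):
    if pv.has("essential_tremor"):
        return _each(pv.meds("levodopa_dopamine_agonist"))
    return []


@rule("D23", "levodopa or dopamine agonist for drug-induced parkinsonism")
def _d23(pv):
    if pv.has("drug_induced_parkinsonism"):
        return _each(pv.meds("levodopa_dopamine_agonist"))
    return []


@rule("D24", "first-generation antihistamine as first-line treatment for allergy or pruritus")
def _d24(pv):
    if not pv.has("allergy_pruritus"):
        return []
    if pv.on("second_gen_antihistamine"):
        return []
    return _each(pv.meds("first_gen_antihistamine"))


@rule("D25", "first-generation antihistamine for insomnia")
def _d25(pv):
    if pv.has("insomnia"):
        return _each(pv.meds("first_gen_antihistamine"))
    return []


# =========================================================================
# Section E — renal system (eGFR thresholds in mL/min/1.73 m^2)
# =========================================================================

def _egfr_rule(pv, subjects, below: float):
    if not subjects:
        return []
    egfr = pv.lab("egfr")
    if egfr is None:
        return NotEvaluable("egfr")
    return _each(subjects) if egfr < below else []


@rule("E1", "long-term digoxin at 125 ug/day or more with eGFR below 30")
def _e1(pv):
    subjects = [m for m in pv.meds("digoxin", min_days=91) if m.dose_mg >= 0.125]
    return _egfr_rule(pv, subjects, 30.0)


@rule("E2", "direct thrombin inhibitor with eGFR below 30")
def _e2(pv):
    return _egfr_rule(pv, pv.meds("direct_thrombin_inhibitor"), 30.0)


@rule("E3", "factor Xa inhibitor with eGFR below 15")
def _e3(pv):
    return _egfr_rule(pv, pv.meds("factor_xa_inhibitor"), 15.0)


@rule("E4", "NSAID with eGFR below 50")
def _e4(pv):
    return _egfr_rule(pv, pv.meds("nsaid", "aspirin"), 50.0)


@rule("E5", "colchicine with eGFR below 10")
def _e5(pv):
    return _egfr_rule(pv, pv.meds("colchicine"), 10.0)


@rule("E6", "metformin with eGFR below 30")
def _e6(pv):
    return _egfr_rule(pv, pv.meds("metformin"), 30.0)


@rule("E7", "mineralocorticoid receptor antagonist with eGFR below 30")
def _e7(pv):
    return _egfr_rule(pv, pv.meds("aldosterone_antagonist"), 30.0)


@rule("E8", "nitrofurantoin with eGFR below 45")
def _e8(pv):
    return _egfr_rule(pv, pv.meds("nitrofurantoin"), 45.0)


@rule("E9", "bisphosphonate with eGFR below 30")
def _e9(pv):
    return _egfr_rule(pv, pv.meds("bisphosphonate"), 30.0)


@rule("E10", "methotrexate with eGFR below 30")
def _e10(pv):
    return _egfr_rule(pv, pv.meds("methotrexate"), 30.0)


# =========================================================================
# Section F — gastrointestinal system
# =========================================================================

@rule("F1", "prochlorperazine or metoclopramide with parkinsonism")
def _f1(pv):
    if pv.has("parkinsonism", "lewy_body_dementia"):
        return _each(pv.meds("metoclopramide_prochlorperazine"))
    return []


@rule("F2", "full-dose PPI for uncomplicated ulcer or esophagitis beyond 8 weeks")
def _f2(pv):
    if not pv.has("peptic_ulcer_disease", "erosive_esophagitis"):
        return []
    out = []
    for m in pv.meds("ppi", min_days=57):
        full = PPI_FULL_DOSE.get(m.atc_code, 20.0)
        if m.dose_mg >= full:
            out.append((m,))
    return out


@rule("F3", "constipating drug in chronic constipation")
def _f3(pv):
    if pv.has("chronic_constipation"):
        return _each(pv.meds("constipating", "anticholinergic", "oral_iron", "opioid"))
    return []


@rule("F4", "oral iron above the ceiling of useful absorption")
def _f4(pv):
    out = []
    for m in pv.meds("oral_iron"):
        limit = IRON_DOSE_LIMITS.get(m.atc_code, 600.0)
        if m.dose_mg > limit:
            out.append((m,))
    return out


@rule("F5", "corticosteroid with peptic ulcer history and no gastroprotection")
def _f5(pv):
    if not pv.has("peptic_ulcer_disease", "erosive_esophagitis"):
        return []
    if pv.on("ppi"):
        return []
    return _each(pv.meds("systemic_corticosteroid"))


@rule("F6", "antiplatelet or anticoagulant with gastric antral vascular ectasia")
def _f6(pv):
    if pv.has("gave"):
        return _each(pv.meds("antiplatelet", *ANTICOAG))
    return []


@rule("F7", "antipsychotic with dysphagia")
def _f7(pv):
    if pv.has("dysphagia"):
        return _each(pv.meds("antipsychotic"))
    return []


@rule("F8", "megestrol acetate to increase appetite")
def _f8(pv):
    return _each(pv.meds("megestrol"))


# =========================================================================
# Section G — respiratory system
# =========================================================================

@rule("G1", "theophylline as monotherapy for COPD")
def _g1(pv):
    if not pv.has("copd"):
        return []
    if pv.on("inhaled_corticosteroid", "lama", "inhaled_beta_agonist"):
        return []
    return _each(pv.meds("theophylline"))


@rule("G2", "systemic instead of inhaled corticosteroid for maintenance in COPD")
def _g2(pv):
    if not pv.has("copd"):
        return []
    if pv.on("inhaled_corticosteroid"):
        return []
    return _each(pv.meds("systemic_corticosteroid", route_in=("oral", "parenteral")))


@rule("G3", "long-acting muscarinic antagonist with narrow-angle glaucoma or bladder outflow obstruction")
def _g3(pv):
    if pv.has("narrow_angle_glaucoma", "bph_luts", "urinary_retention_history"):
        return _each(pv.meds("lama"))
    return []


@rule("G4", "benzodiazepine with acute or chronic respiratory failure")
def _g4(pv):
    subjects = pv.meds("benzodiazepine")
    if not subjects:
        return []
    if pv.has("respiratory_failure"):
        return _each(subjects)
    return _lab_gate(pv, subjects, [
        ("po2_kpa", lambda v: v < 8.0),
        ("pco2_kpa", lambda v: v > 6.5),
    ])


# =========================================================================
# Section H — musculoskeletal system
# =========================================================================

@rule("H1", "non-selective NSAID with ulcer history and no gastroprotection")
def _h1(pv):
    if not pv.has("peptic_ulcer_disease", "gi_bleed_history"):
        return []
    if pv.on("ppi", "h2_antagonist"):
        return []
    return _each(pv.meds("nsaid_nonselective"))


@rule("H2", "NSAID with severe hypertension")
def _h2(pv):
    return _lab_gate(pv, pv.meds("nsaid"), [
        ("systolic_bp", lambda v: v > 170.0),
        ("diastolic_bp", lambda v: v > 100.0),
    ])


@rule("H3", "long-term NSAID for osteoarthritis pain without trying paracetamol")
def _h3(pv):
    if not pv.has("osteoarthritis"):
        return []
    if pv.on("paracetamol"):
        return []
    return _each(pv.meds("nsaid", min_days=91))


@rule("H4", "long-term corticosteroid monotherapy for rheumatoid arthritis")
def _h4(pv):
    if not pv.has("rheumatoid_arthritis"):
        return []
    if pv.on("methotrexate"):
        return []
    return _each(pv.meds("systemic_corticosteroid", min_days=91))


@rule("H5", "corticosteroid for osteoarthritis")
def _h5(pv):
    if pv.has("osteoarthritis"):
        return _each(pv.meds("systemic_corticosteroid"))
    return []


@rule("H6", "long-term NSAID or colchicine for gout prophylaxis instead of a xanthine-oxidase inhibitor")
def _h6(pv):
    if not pv.has("gout") or pv.has("xanthine_oxidase_contraindicated"):
        return []
    if pv.on("xanthine_oxidase_inhibitor"):
        return []
    return _each(pv.meds("nsaid", "colchicine", min_days=91))


@rule("H7", "NSAID with concurrent corticosteroid for arthritis or rheumatism")
def _h7(pv):
    if not pv.has("osteoarthritis", "rheumatoid_arthritis", "gout"):
        return []
    return _pairs(pv.meds("nsaid"), pv.meds("systemic_corticosteroid"))


@rule("H8", "oral bisphosphonate with upper gastrointestinal disease")
def _h8(pv):
    if not pv.has("dysphagia", "erosive_esophagitis", "peptic_ulcer_disease",
                  "gi_bleed_history", "upper_gi_disease"):
        return []
    return _each(pv.meds("bisphosphonate", route_in=("oral",)))


@rule("H9", "long-term opioid for osteoarthritis")
def _h9(pv):
    if pv.has("osteoarthritis"):
        return _each(pv.meds("opioid", min_days=91))
    return []


# =========================================================================
# Section I — urogenital system
# =========================================================================

@rule("I1", "bladder antimuscarinic in dementia or chronic cognitive impairment")
def _i1(pv):
    if pv.has("dementia", "lewy_body_dementia", "delirium"):
        return _each(pv.meds("urological_antimuscarinic"))
    return []


@rule("I2", "bladder antimuscarinic with narrow-angle glaucoma")
def _i2(pv):
    if pv.has("narrow_angle_glaucoma"):
        return _each(pv.meds("urological_antimuscarinic"))
    return []


@rule("I3", "bladder antimuscarinic with prostatic symptoms and high post-void residual")
def _i3(pv):
    if pv.has("bph_luts") and pv.has("high_post_void_residual"):
        return _each(pv.meds("urological_antimuscarinic"))
    return []


@rule("I4", "bladder antimuscarinic with constipation")
def _i4(pv):
    if pv.has("chronic_constipation"):
        return _each(pv.meds("urological_antimuscarinic"))
    return []


@rule("I5", "non-silodosin alpha-1 blocker with orthostatic hypotension or syncope")
def _i5(pv):
    if pv.has("orthostatic_hypotension", "syncope_history"):
        return _each(pv.meds("alpha1_blocker"))
    return []


@rule("I6", "mirabegron in labile or severe hypertension")
def _i6(pv):
    return _lab_gate(pv, pv.meds("mirabegron"),
                     [("systolic_bp", lambda v: v > 180.0)])


@rule("I7", "duloxetine with urinary urgency or urge incontinence")
def _i7(pv):
    if pv.has("urge_incontinence", "overactive_bladder"):
        return _each([m for m in pv.meds("snri") if m.atc_code == "N06AX21"])
    return []


@rule("I8", "antibiotic for asymptomatic bacteriuria")
def _i8(pv):
    if pv.has("asymptomatic_bacteriuria"):
        return _each(pv.meds("antibiotic"))
    return []


# =========================================================================
# Section J — endocrine system
# =========================================================================

@rule("J1", "long-acting sulfonylurea in type 2 diabetes")
def _j1(pv):
    if pv.has("diabetes_type2", "diabetes_complicated"):
        return _each(pv.meds("sulfonylurea_long_acting"))
    return []


@rule("J2", "thiazolidinedione with heart failure")
def _j2(pv):
    if pv.has("heart_failure", "heart_failure_preserved_ef", "heart_failure_nyha_3_4"):
        return _each(pv.meds("thiazolidinedione"))
    return []


@rule("J3", "nonselective beta-blocker in diabetes with frequent hypoglycemia")
def _j3(pv):
    if pv.has("diabetes_type2", "diabetes_complicated") and pv.has("frequent_hypoglycemia"):
        return _each(pv.meds("beta_blocker_nonselective"))
    return []


@rule("J4", "SGLT2 inhibitor with symptomatic hypotension")
def _j4(pv):
    if pv.has("symptomatic_hypotension"):
        return _each(pv.meds("sglt2_inhibitor"))
    return []


@rule("J5", "systemic estrogen with a history of breast cancer")
def _j5(pv):
    if pv.has("breast_cancer"):
        return _each(pv.meds("systemic_estrogen"))
    return []


@rule("J6", "systemic estrogen with a history of venous thromboembolism")
def _j6(pv):
    if pv.has("vte_history"):
        return _each(pv.meds("systemic_estrogen"))
    return []


@rule("J7", "menopausal hormone therapy with stenotic arterial disease")
def _j7(pv):
    if not pv.has(*CVD_CONDITIONS):
        return []
    estrogens = pv.meds("systemic_estrogen")
    progestins = pv.meds("progestogen")
    return _pairs(estrogens, progestins)


@rule("J8", "unopposed systemic estrogen with an intact uterus")
def _j8(pv):
    if not pv.has("intact_uterus"):
        return []
    if pv.on("progestogen"):
        return []
    return _each(pv.meds("systemic_estrogen"))


@rule("J9", "levothyroxine in subclinical hypothyroidism")
def _j9(pv):
    subjects = pv.meds("levothyroxine")
    if not subjects:
        return []
    tsh = pv.lab("tsh_mu_l")
    t4 = pv.patient.labs.free_t4_status
    missing = [name for name, v in (("tsh_mu_l", tsh), ("free_t4_status", t4))
               if v is None]
    if missing:
        return NotEvaluable(*missing)
    if t4 == "normal" and TSH_UPPER_NORMAL < tsh < 10.0:
        return _each(subjects)
    return []


@rule("J10", "vasopressin analog for urinary incontinence or frequency")
def _j10(pv):
    if pv.has("urinary_incontinence", "urge_incontinence"):
        return _each(pv.meds("vasopressin_analog"))
    return []


# =========================================================================
# Section K — drugs that predictably increase falls risk
# =========================================================================

def _falls(pv) -> bool:
    return pv.has("recurrent_falls")


@rule("K1", "benzodiazepine with recurrent falls")
def _k1(pv):
    return _each(pv.meds("benzodiazepine")) if _falls(pv) else []


@rule("K2", "antipsychotic with recurrent falls")
def _k2(pv):
    return _each(pv.meds("antipsychotic")) if _falls(pv) else []


@rule("K3", "vasodilator with recurrent falls and persistent postural hypotension")
def _k3(pv):
    if _falls(pv) and pv.has("orthostatic_hypotension"):
        return _each(pv.meds("vasodilator"))
    return []


@rule("K4", "hypnotic Z-drug with recurrent falls")
def _k4(pv):
    return _each(pv.meds("z_drug")) if _falls(pv) else []


@rule("K5", "antiepileptic with recurrent falls")
def _k5(pv):
    return _each(pv.meds("antiepileptic")) if _falls(pv) else []


@rule("K6", "first-generation antihistamine with recurrent falls")
def _k6(pv):
    return _each(pv.meds("first_gen_antihistamine")) if _falls(pv) else []


@rule("K7", "opioid with recurrent falls")
def _k7(pv):
    return _each(pv.meds("opioid")) if _falls(pv) else []


@rule("K8", "antidepressant with recurrent falls")
def _k8(pv):
    return _each(pv.meds("antidepressant")) if _falls(pv) else []


@rule("K9", "alpha-blocker as antihypertensive with recurrent falls")
def _k9(pv):
    if _falls(pv) and pv.has("hypertension"):
        return _each(pv.meds("alpha1_blocker"))
    return []


@rule("K10", "non-silodosin alpha-blocker for prostatic symptoms with recurrent falls")
def _k10(pv):
    if _falls(pv) and pv.has("bph_luts"):
        return _each(pv.meds("alpha1_blocker"))
    return []


@rule("K11", "centrally acting antihypertensive with recurrent falls")
def _k11(pv):
    return _each(pv.meds("central_antihypertensive")) if _falls(pv) else []


@rule("K12", "bladder antimuscarinic for overactive bladder with recurrent falls")
def _k12(pv):
    if _falls(pv) and pv.has("overactive_bladder", "urge_incontinence"):
        return _each(pv.meds("urological_antimuscarinic"))
    return []


# =========================================================================
# Section L — analgesic drugs
# =========================================================================

@rule("L1", "strong opioid as first-line therapy for mild pain")
def _l1(pv):
    if not pv.has("mild_pain"):
        return []
    if pv.on("paracetamol") or pv.on("nsaid"):
        return []
    return _each(pv.meds("opioid_strong", route_in=("oral", "transdermal")))


@rule("L2", "regular opioid without a concomitant laxative")
def _l2(pv):
    if pv.on("laxative"):
        return []
    return _each(pv.meds("opioid", regular=True))


@rule("L3", "long-acting opioid without a short-acting opioid for breakthrough pain")
def _l3(pv):
    long_acting = pv.meds("opioid_long_acting")
    if not long_acting:
        return []
    short_acting = [m for m in pv.meds("opioid")
                    if "opioid_long_acting" not in pv.tags_of(m)]
    if short_acting:
        return []
    return _each(long_acting)


@rule("L4", "topical lidocaine patch for chronic osteoarthritis pain")
def _l4(pv):
    if pv.has("osteoarthritis"):
        return _each(pv.meds("lidocaine_patch", route_in=("topical", "transdermal")))
    return []


@rule("L5", "gabapentinoid for non-neuropathic pain")
def _l5(pv):
    if pv.has("non_neuropathic_pain") and not pv.has("neuropathic_pain"):
        return _each(pv.meds("gabapentinoid"))
    return []


@rule("L6", "high-dose paracetamol with poor nutritional status or chronic liver disease")
def _l6(pv):
    subjects = [m for m in pv.meds("paracetamol") if m.dose_mg >= 3000.0]
    if not subjects:
        return []
    if pv.has("liver_disease_mild", "liver_disease_severe"):
        return _each(subjects)
    bmi = pv.lab("bmi")
    if bmi is None:
        return NotEvaluable("bmi")
    return _each(subjects) if bmi < 18.0 else []


# =========================================================================
# Section M — antimuscarinic/anticholinergic drug burden
# =========================================================================

@rule("M1", "concomitant use of two or more drugs with antimuscarinic properties")
def _m1(pv):
    members = pv.meds("anticholinergic", regular=True)
    seen: set[str] = set()
    distinct = []
    for m in members:
        if m.atc_code not in seen:
            seen.add(m.atc_code)
            distinct.append(m)
    if len(distinct) >= 2:
        return [tuple(distinct)]
    return []


assert len(CRITERIA) == 133, f"expected 133 criteria, registered {len(CRITERIA)}"
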