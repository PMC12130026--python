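"""Canonical triggering constructions for every criterion.

Each recipe is a minimal medication/condition/lab constellation that fires
its criterion.  They serve three purposes: per-criterion unit fixtures, the
building blocks the synthetic generator attaches when a criterion-trigger
rate is requested, and documentation of what each predicate needs.

``lab_dependent`` lists the laboratory fields whose absence makes the
criterion *not evaluable* when the drug clause alone is satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cohort import LabPanel, MedicationOrder, PatientRecord


def med(
    code: str,
    dose: float = 0.0,
    unit: str = "mg",
    route: str = "oral",
    prn: bool = False,
    days: int = 10,
    indication: Optional[str] = None,
    name: str = "",
) -> MedicationOrder:
    return MedicationOrder(
        atc_code=code, name=name, daily_dose=dose, dose_unit=unit,
        route=route, prn=prn, duration_days=days, indication_code=indication,
    )


@dataclass(frozen=True)
class Recipe:
    criterion_id: str
    meds: tuple[MedicationOrder, ...]
    conditions: frozenset[str] = frozenset()
    labs: dict = field(default_factory=dict)
    age: int = 70
    sex: str = "male"
    lab_dependent: tuple[str, ...] = ()

    def patient(self, patient_id: str = "RX") -> PatientRecord:
        return PatientRecord(
            patient_id=patient_id, age_years=self.age, sex=self.sex,
            conditions=self.conditions, labs=LabPanel(**self.labs),
            medications=self.meds,
        )

    def patient_without_labs(self, patient_id: str = "RX-NL") -> PatientRecord:
        """Drug clause satisfied, conditions and labs stripped: the
        not-evaluable probe for lab-dependent criteria."""
        return PatientRecord(
            patient_id=patient_id, age_years=self.age, sex=self.sex,
            conditions=frozenset(), labs=LabPanel(), medications=self.meds,
        )

    def patient_without_subject(self, patient_id: str = "RX-NT") -> PatientRecord:
        """Conditions and labs kept, offending drugs replaced by an inert
        one: the not-triggered probe."""
        return PatientRecord(
            patient_id=patient_id, age_years=self.age, sex=self.sex,
            conditions=self.conditions, labs=LabPanel(**self.labs),
            medications=(med("A11BA01", 1, days=30),),
        )


def _r(cid, meds, conds=(), labs=None, age=70, sex="male", lab_dep=()):
    return Recipe(
        criterion_id=cid, meds=tuple(meds), conditions=frozenset(conds),
        labs=dict(labs or {}), age=age, sex=sex, lab_dependent=tuple(lab_dep),
    )


TRIGGER_RECIPES: dict[str, Recipe] = {r.criterion_id: r for r in [
    # A — indication
    _r("A1", [med("B01AB05", 40, route="parenteral", days=5,
                  indication="no_indication")]),
    _r("A2", [med("J01CA04", 1500, days=20)]),
    _r("A3", [med("N06AB06", 50, days=30), med("N06AB10", 10, days=30)]),
    # B — cardiovascular
    _r("B1", [med("C01AA05", 0.25, days=30)], ["heart_failure_preserved_ef"]),
    _r("B2", [med("C08DA01", 120, days=30)], ["heart_failure_nyha_3_4"]),
    _r("B3", [med("C07AB03", 50, days=30), med("C08DA01", 120, days=30)]),
    _r("B4", [med("C07AB02", 50, days=30)], ["bradycardia"], lab_dep=["heart_rate"]),
    _r("B5", [med("C07AB03", 50, days=60)], ["hypertension"]),
    _r("B6", [med("C01BD01", 200, days=30)], ["supraventricular_tachyarrhythmia"]),
    _r("B7", [med("C03CA01", 40, days=60)], ["hypertension"]),
    _r("B8", [med("C03CA01", 40, days=30)], ["dependent_ankle_edema"]),
    _r("B9", [med("C03AA03", 25, days=30)], labs={"serum_k": 2.5},
       lab_dep=["serum_k", "serum_na", "corrected_ca"]),
    _r("B10", [med("C03CA01", 40, days=30)], ["hypertension", "urinary_incontinence"]),
    _r("B11", [med("C02AC01", 0.1, days=30)]),
    _r("B12", [med("C09AA03", 10, days=30)], labs={"serum_k": 5.8}, lab_dep=["serum_k"]),
    _r("B13", [med("C03DA01", 25, days=30), med("C09AA03", 10, days=30)]),
    _r("B14", [med("G04BE03", 50, days=10)], labs={"systolic_bp": 85},
       lab_dep=["systolic_bp"]),
    _r("B15", [med("J01FA09", 500, days=5)], labs={"qtc_ms": 480}, lab_dep=["qtc_ms"]),
    _r("B16", [med("C10AA05", 20, days=120)], ["frailty_limited_life_expectancy"], age=86),
    _r("B17", [med("M01AE01", 1200, days=120)], ["coronary_artery_disease"]),
    _r("B18", [med("N05AX08", 2, days=120)], ["coronary_artery_disease"]),
    _r("B19", [med("M01AE01", 1200, days=20), med("C03CA01", 40, days=30)],
       ["heart_failure"]),
    _r("B20", [med("C07AB03", 50, days=30)], ["severe_symptomatic_aortic_stenosis"]),
    _r("B21", [med("C01AA05", 0.25, days=120)], ["atrial_fibrillation"]),
    # C — coagulation
    _r("C1", [med("B01AC06", 150, days=120)], ["coronary_artery_disease"]),
    _r("C2", [med("B01AC06", 75, days=30)], ["recent_bleeding", "coronary_artery_disease"]),
    _r("C3", [med("B01AC06", 75, days=60), med("B01AC04", 75, days=60)], ["stroke"]),
    _r("C4", [med("B01AC06", 75, days=60), med("B01AA03", 5, days=60)],
       ["atrial_fibrillation", "metallic_heart_valve"]),
    _r("C5", [med("B01AC06", 75, days=60), med("B01AA03", 5, days=60)],
       ["coronary_artery_disease"]),
    _r("C6", [med("B01AC05", 250, days=30)]),
    _r("C7", [med("B01AC06", 75, days=60)], ["atrial_fibrillation"]),
    _r("C8", [med("B01AA03", 5, days=200)], ["first_dvt"]),
    _r("C9", [med("B01AA03", 5, days=200)], ["first_pe"]),
    _r("C10", [med("M01AB05", 100, days=10), med("B01AA03", 5, days=60)]),
    _r("C11", [med("B01AA03", 5, days=60)], ["atrial_fibrillation"]),
    _r("C12", [med("N06AB06", 50, days=60), med("B01AA03", 5, days=60)],
       ["bleeding_history_major"]),
    _r("C13", [med("B01AE07", 300, days=30), med("C08DA01", 120, days=30)]),
    _r("C14", [med("B01AF01", 20, days=30), med("C08DA01", 120, days=30)]),
    _r("C15", [med("G03CA03", 1, days=60)], ["vte_history"], sex="female"),
    _r("C16", [med("B01AC06", 75, days=60)]),
    # D — central nervous system
    _r("D1", [med("N06AA09", 25, days=30)], ["dementia"]),
    _r("D2", [med("N06AA09", 25, days=30)], ["depression"]),
    _r("D3", [med("N06AX16", 75, days=30)], labs={"systolic_bp": 190},
       lab_dep=["systolic_bp", "diastolic_bp"]),
    _r("D4", [med("N05AH03", 5, days=30)], ["bph_luts"]),
    _r("D5", [med("N05AX08", 1, days=100)], ["bpsd"]),
    _r("D6", [med("N06AB06", 50, days=30)], labs={"serum_na": 126}, lab_dep=["serum_na"]),
    _r("D7", [med("N06AB06", 50, days=30)], ["recent_bleeding"]),
    _r("D8", [med("N03AE01", 0.5, days=35)]),
    _r("D9", [med("N05BA06", 1, days=10)], ["bpsd"]),
    _r("D10", [med("N03AE01", 0.5, days=15)], ["insomnia"]),
    _r("D11", [med("N05CF01", 7.5, days=15)], ["insomnia"]),
    _r("D12", [med("N05AX08", 1, days=10)], ["parkinsonism"]),
    _r("D13", [med("N04AA04", 7.5, days=30), med("N05AD01", 2, days=30)]),
    _r("D14", [med("R06AD02", 25, days=10)], ["dementia"]),
    _r("D15", [med("N05AX08", 1, days=100)], ["bpsd"]),
    _r("D16", [med("N05AX08", 1, days=10)], ["insomnia"]),
    _r("D17", [med("N06DA02", 5, days=60)], ["bradycardia"], lab_dep=["heart_rate"]),
    _r("D18", [med("N06DA02", 5, days=60), med("C07AB03", 50, days=60)]),
    _r("D19", [med("N06DX01", 10, days=60)], ["epilepsy"]),
    _r("D20", [med("N06BX03", 2400, days=60)], ["dementia"]),
    _r("D21", [med("N05AA01", 50, days=30)], ["psychosis"]),
    _r("D22", [med("N04BA02", 300, days=60)], ["essential_tremor"]),
    _r("D23", [med("N04BA02", 300, days=60)], ["drug_induced_parkinsonism"]),
    _r("D24", [med("D04AA16", 25, days=7)], ["allergy_pruritus"]),
    _r("D25", [med("D04AA16", 25, days=7)], ["insomnia"]),
    # E — renal
    _r("E1", [med("C01AA05", 250, unit="ug", days=100)], labs={"egfr": 25},
       lab_dep=["egfr"]),
    _r("E2", [med("B01AE07", 300, days=30)], labs={"egfr": 25}, lab_dep=["egfr"]),
    _r("E3", [med("B01AF01", 20, days=30)], labs={"egfr": 12}, lab_dep=["egfr"]),
    _r("E4", [med("M01AB05", 75, days=30)], labs={"egfr": 40}, lab_dep=["egfr"]),
    _r("E5", [med("M04AC01", 1, days=30)], labs={"egfr": 8}, lab_dep=["egfr"]),
    _r("E6", [med("A10BA02", 1000, days=60)], ["diabetes_type2"],
       labs={"egfr": 25}, lab_dep=["egfr"]),
    _r("E7", [med("C03DA01", 25, days=30)], labs={"egfr": 25}, lab_dep=["egfr"]),
    _r("E8", [med("J01XE01", 100, days=5)], labs={"egfr": 40}, lab_dep=["egfr"]),
    _r("E9", [med("M05BA04", 70, days=60)], labs={"egfr": 25}, lab_dep=["egfr"]),
    _r("E10", [med("L04AX03", 10, days=60)], labs={"egfr": 25}, lab_dep=["egfr"]),
    # F — gastrointestinal
    _r("F1", [med("A03FA01", 30, days=10)], ["parkinsonism"]),
    _r("F2", [med("A02BC01", 20, days=70)], ["peptic_ulcer_disease"]),
    _r("F3", [med("B03AA07", 200, days=30)], ["chronic_constipation"]),
    _r("F4", [med("B03AA07", 800, days=30)]),
    _r("F5", [med("H02AB06", 10, days=20)], ["peptic_ulcer_disease"]),
    _r("F6", [med("B01AC06", 75, days=30)], ["gave", "coronary_artery_disease"]),
    _r("F7", [med("N05AX08", 1, days=10)], ["dysphagia"]),
    _r("F8", [med("L02AB01", 160, days=30)]),
    # G — respiratory
    _r("G1", [med("R03DA04", 200, days=60)], ["copd"]),
    _r("G2", [med("H02AB09", 100, route="parenteral", days=5)], ["copd"]),
    _r("G3", [med("R03BB04", 18, unit="ug", route="inhaled", days=60)],
       ["narrow_angle_glaucoma"]),
    _r("G4", [med("N05BA01", 5, days=10)], ["respiratory_failure"],
       lab_dep=["po2_kpa", "pco2_kpa"]),
    # H — musculoskeletal
    _r("H1", [med("M01AE01", 1200, days=10)], ["peptic_ulcer_disease"]),
    _r("H2", [med("M01AB05", 100, days=10)], labs={"systolic_bp": 180},
       lab_dep=["systolic_bp", "diastolic_bp"]),
    _r("H3", [med("M01AE02", 500, days=100)], ["osteoarthritis"]),
    _r("H4", [med("H02AB06", 10, days=100)], ["rheumatoid_arthritis"]),
    _r("H5", [med("H02AB09", 20, days=20)], ["osteoarthritis"]),
    _r("H6", [med("M01AE02", 500, days=100)], ["gout"]),
    _r("H7", [med("M01AE01", 1200, days=20), med("H02AB06", 10, days=20)],
       ["osteoarthritis"]),
    _r("H8", [med("M05BA04", 70, days=60)], ["peptic_ulcer_disease"]),
    _r("H9", [med("N02AA01", 30, days=100)], ["osteoarthritis"]),
    # I — urogenital
    _r("I1", [med("G04BD04", 5, days=30)], ["dementia"]),
    _r("I2", [med("G04BD04", 5, days=30)], ["narrow_angle_glaucoma"]),
    _r("I3", [med("G04BD04", 5, days=30)], ["bph_luts", "high_post_void_residual"]),
    _r("I4", [med("G04BD04", 5, days=30)], ["chronic_constipation"]),
    _r("I5", [med("G04CA02", 0.4, days=60)],
       ["orthostatic_hypotension", "syncope_history", "bph_luts"]),
    _r("I6", [med("G04BD12", 50, days=30)], labs={"systolic_bp": 190},
       lab_dep=["systolic_bp"]),
    _r("I7", [med("N06AX21", 60, days=30)], ["urge_incontinence"]),
    _r("I8", [med("J01CA04", 1500, days=5)], ["asymptomatic_bacteriuria"]),
    # J — endocrine
    _r("J1", [med("A10BB12", 2, days=60)], ["diabetes_type2"]),
    _r("J2", [med("A10BG03", 15, days=60)], ["heart_failure"]),
    _r("J3", [med("C07AA05", 80, days=60)], ["diabetes_type2", "frequent_hypoglycemia"]),
    _r("J4", [med("A10BK03", 10, days=30)], ["symptomatic_hypotension"]),
    _r("J5", [med("G03CA03", 1, days=60)], ["breast_cancer"], sex="female"),
    _r("J6", [med("G03CA03", 1, days=60)], ["vte_history"], sex="female"),
    _r("J7", [med("G03CA03", 1, days=60), med("G03DA04", 100, days=60)],
       ["coronary_artery_disease"], sex="female"),
    _r("J8", [med("G03CA03", 1, days=60)], ["intact_uterus"], sex="female"),
    _r("J9", [med("H03AA01", 50, unit="ug", days=60)],
       labs={"tsh_mu_l": 7.0, "free_t4_status": "normal"}, lab_dep=["tsh_mu_l"]),
    _r("J10", [med("H01BA02", 0.2, days=30)], ["urinary_incontinence"]),
    # K — falls risk
    _r("K1", [med("N05BA01", 5, days=10)], ["recurrent_falls"]),
    _r("K2", [med("N05AX08", 1, days=10)], ["recurrent_falls"]),
    _r("K3", [med("C02DB02", 75, days=30)],
       ["recurrent_falls", "orthostatic_hypotension"]),
    _r("K4", [med("N05CF01", 7.5, days=10)], ["recurrent_falls"]),
    _r("K5", [med("N03AG01", 500, days=60)], ["recurrent_falls"]),
    _r("K6", [med("R06AB04", 4, days=7)], ["recurrent_falls"]),
    _r("K7", [med("N02AX02", 100, days=10), med("A06AB06", 15, days=10)],
       ["recurrent_falls"]),
    _r("K8", [med("N06AB06", 50, days=30)], ["recurrent_falls"]),
    _r("K9", [med("C02CA04", 4, days=60)], ["recurrent_falls", "hypertension"]),
    _r("K10", [med("G04CA02", 0.4, days=60)], ["recurrent_falls", "bph_luts"]),
    _r("K11", [med("C02AC01", 0.1, days=30)], ["recurrent_falls"]),
    _r("K12", [med("G04BD04", 5, days=30)], ["recurrent_falls", "overactive_bladder"]),
    # L — analgesics
    _r("L1", [med("N02AX02", 100, days=5), med("A06AB06", 15, days=5)], ["mild_pain"]),
    _r("L2", [med("N02AX02", 100, days=10)]),
    _r("L3", [med("N02AB03", 25, unit="ug", route="transdermal", days=30)]),
    _r("L4", [med("N01BB02", 700, route="transdermal", days=30)], ["osteoarthritis"]),
    _r("L5", [med("N02BF02", 150, days=30)], ["non_neuropathic_pain"]),
    _r("L6", [med("N02BE01", 3000, days=10)], labs={"bmi": 16}, lab_dep=["bmi"]),
    # M — anticholinergic burden
    _r("M1", [med("N04AA04", 7.5, days=30), med("R06AD02", 25, days=30)]),
]}

assert len(TRIGGER_RECIPES) == 133
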