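"""Controlled clinical vocabulary.

Every clinical state referenced by a STOPP v3 predicate is encoded as a member
of a closed, versioned condition vocabulary so that rule evaluation is
decidable: a condition is either recorded (present) or not recorded (absent).
Laboratory-dependent states (e.g. hyperkalaemia) are *not* condition codes;
they are read from the numeric lab panel so that a missing measurement can be
distinguished from a normal one (tri-state evaluation).
"""

from __future__ import annotations

VOCABULARY_VERSION = "1.0"

#: Closed condition vocabulary. docs/condition_vocabulary.md maps each code to
#: the clinical phrase it encodes.
CONDITIONS: frozenset[str] = frozenset({
    # cardiovascular
    "heart_failure",
    "heart_failure_preserved_ef",
    "heart_failure_nyha_3_4",
    "atrial_fibrillation",
    "supraventricular_tachyarrhythmia",
    "bradycardia",
    "heart_block",
    "hypertension",
    "uncontrolled_severe_hypertension",
    "severe_symptomatic_aortic_stenosis",
    "angina",
    "aortic_aneurysm",
    "coronary_artery_disease",
    "mi_history",
    "coronary_stent_recent",          # stent inserted within previous 12 months
    "coronary_stenosis_high_grade",   # angiographically proven >50%
    "acute_coronary_syndrome",
    "carotid_stenosis_symptomatic",
    "metallic_heart_valve",
    "mitral_stenosis",                # moderate-to-severe
    "stroke",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
    "orthostatic_hypotension",        # persistent postural drop
    "syncope_history",
    "recurrent_falls",
    # bleeding / coagulation
    "bleeding_diathesis",
    "recent_bleeding",                # recent non-trivial spontaneous bleeding
    "bleeding_history_major",         # previous major haemorrhage
    "gi_bleed_history",
    "gave",                           # gastric antral vascular ectasia
    "first_dvt",
    "first_pe",
    "vte_history",
    "persistent_vte_risk",            # continuing provoking risk factors
    # gastrointestinal
    "peptic_ulcer_disease",
    "erosive_esophagitis",
    "upper_gi_disease",
    "dysphagia",
    "chronic_constipation",
    # urogenital
    "urinary_incontinence",
    "urge_incontinence",
    "overactive_bladder",
    "bph_luts",                       # lower urinary tract symptoms with BPH
    "urinary_retention_history",
    "high_post_void_residual",        # >200 mL
    "asymptomatic_bacteriuria",
    "nephrotic_syndrome",
    "renal_failure",
    # neuropsychiatric
    "dementia",
    "delirium",
    "bpsd",                           # behavioural/psychological symptoms of dementia
    "bpsd_severe_refractory",
    "parkinsonism",
    "drug_induced_parkinsonism",
    "lewy_body_dementia",
    "epilepsy",
    "essential_tremor",
    "depression",
    "psychosis",
    "insomnia",
    "narrow_angle_glaucoma",
    # respiratory
    "copd",
    "respiratory_failure",
    # musculoskeletal / metabolic
    "dependent_ankle_edema",
    "gout",
    "osteoarthritis",
    "rheumatoid_arthritis",
    "connective_tissue_disease",
    "diabetes_type2",
    "diabetes_complicated",           # diabetes with end-organ damage
    "frequent_hypoglycemia",
    "symptomatic_hypotension",
    # oncology / endocrine / misc
    "breast_cancer",
    "cancer",
    "metastatic_cancer",
    "intact_uterus",
    "liver_disease_mild",
    "liver_disease_severe",
    "hemiplegia",
    "aids",
    "allergy_pruritus",
    "mild_pain",
    "neuropathic_pain",
    "non_neuropathic_pain",
    "frailty_limited_life_expectancy",
    "antihypertensive_intolerance",   # intolerance of / failure on other classes
    "xanthine_oxidase_contraindicated",
})

#: The 13 physiological-system sections of the STOPP v3 screening tool.
SYSTEM_GROUPS: dict[str, str] = {
    "A": "indication",
    "B": "cardiovascular",
    "C": "coagulation",
    "D": "central_nervous_system",
    "E": "renal",
    "F": "gastrointestinal",
    "G": "respiratory",
    "H": "musculoskeletal",
    "I": "urogenital",
    "J": "endocrine",
    "K": "falls_risk",
    "L": "analgesic",
    "M": "anticholinergic_burden",
}

#: Established cardiovascular disease: presence of any of these makes
#: antithrombotic / statin use "secondary prevention".
CVD_CONDITIONS: frozenset[str] = frozenset({
    "coronary_artery_disease",
    "mi_history",
    "acute_coronary_syndrome",
    "stroke",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
})

#: Chronic conditions counted by the none / comorbidity / multimorbidity
#: trichotomy: the chronic diseases recorded at data collection (diabetes,
#: cancer, cerebrovascular accident, hypertension, coronary artery disease)
#: plus the cardio-/cerebrovascular block of the Charlson index.
CHRONIC_COMORBIDITIES: frozenset[str] = frozenset({
    "diabetes_type2",
    "diabetes_complicated",
    "cancer",
    "metastatic_cancer",
    "breast_cancer",
    "stroke",
    "cerebrovascular_disease",
    "hypertension",
    "coronary_artery_disease",
    "mi_history",
    "angina",
    "atrial_fibrillation",
    "peripheral_vascular_disease",
    "heart_failure",
    "heart_failure_preserved_ef",
    "heart_failure_nyha_3_4",
})
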