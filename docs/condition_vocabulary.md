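# Condition vocabulary (version 1.0)

Closed vocabulary of clinical states referenced by the screening rules.
Each code maps to the clinical phrase it encodes; the right-hand column
lists rules that read it (non-exhaustive).  Laboratory-defined states
(hyperkalaemia, hyponatraemia, hypotension by blood pressure, renal function
by eGFR, QTc prolongation, blood-gas respiratory failure, low BMI) are read
from the numeric lab panel, not from condition codes.

| Code | Clinical state | Used by (examples) |
|---|---|---|
| `heart_failure` | heart failure (any) | B19, J2, B5/B7/B8 exclusions |
| `heart_failure_preserved_ef` | heart failure with preserved systolic function | B1 |
| `heart_failure_nyha_3_4` | NYHA class III-IV heart failure | B2 |
| `atrial_fibrillation` | atrial fibrillation | B21, C4, C7, C11; C16 exclusion |
| `supraventricular_tachyarrhythmia` | supraventricular tachyarrhythmia | B6 |
| `bradycardia` | persistent bradycardia | B4, D17 |
| `heart_block` | type II or complete heart block | B4, D1, D17 |
| `hypertension` | hypertension | B5, B7, B10, K9 |
| `uncontrolled_severe_hypertension` | uncontrolled severe hypertension | C2 |
| `severe_symptomatic_aortic_stenosis` | severe symptomatic aortic stenosis | B20 |
| `angina` | angina pectoris | B5 exclusion |
| `aortic_aneurysm` | aortic aneurysm | B5 exclusion; CCI vascular |
| `coronary_artery_disease` | coronary artery disease | B17, B18, C5, J7; C16 exclusion |
| `mi_history` | prior myocardial infarction | CCI; secondary-prevention context |
| `coronary_stent_recent` | coronary stent inserted < 12 months ago | C3, C4 exclusions |
| `coronary_stenosis_high_grade` | angiographically proven > 50% coronary stenosis | C4 exclusion |
| `acute_coronary_syndrome` | current acute coronary syndrome | C3 exclusion |
| `carotid_stenosis_symptomatic` | high-grade symptomatic carotid stenosis | C3, C16 exclusions |
| `metallic_heart_valve` | metallic heart valve in situ | C11 exclusion, C5 exclusion |
| `mitral_stenosis` | moderate-severe mitral stenosis | C11 exclusion |
| `stroke` | prior stroke | C3; CCI cerebrovascular |
| `cerebrovascular_disease` | cerebrovascular disease | B17/B18, C5 |
| `peripheral_vascular_disease` | peripheral vascular disease | B17/B18, C5; CCI |
| `orthostatic_hypotension` | persistent postural hypotension (SBP drop >= 20 / DBP >= 10) | K3, I5 |
| `syncope_history` | recurrent unexplained syncope | I5, D17 |
| `recurrent_falls` | recurrent falls | K1-K12, D1 |
| `bleeding_diathesis` | bleeding diathesis | C2 |
| `recent_bleeding` | recent non-trivial spontaneous bleeding | C2, D7 |
| `bleeding_history_major` | previous major haemorrhage | C12 |
| `gi_bleed_history` | upper gastrointestinal bleeding history | H1, H8 |
| `gave` | gastric antral vascular ectasia | F6 |
| `first_dvt` | first deep venous thrombosis | C8 |
| `first_pe` | first pulmonary embolus | C9 |
| `vte_history` | venous thromboembolism history | C15, J6 |
| `persistent_vte_risk` | continuing provoking VTE risk factors | C8/C9 exclusion |
| `peptic_ulcer_disease` | peptic ulcer disease | F2, F5, H1, H8; CCI |
| `erosive_esophagitis` | erosive peptic esophagitis | F2, F5, H8 |
| `upper_gi_disease` | other upper GI disease (gastritis, duodenitis) | H8 |
| `dysphagia` | dysphagia | F7, H8 |
| `chronic_constipation` | chronic constipation | F3, I4, D1 |
| `urinary_incontinence` | urinary incontinence | B10, J10 |
| `urge_incontinence` | urinary urgency / urge incontinence | I7, J10, K12 |
| `overactive_bladder` | overactive bladder | K12 |
| `bph_luts` | lower urinary tract symptoms with benign prostatic hyperplasia | D4, G3, I3, K10 |
| `urinary_retention_history` | prior urinary retention | D1, D4, G3 |
| `high_post_void_residual` | post-void residual volume > 200 mL | I3 |
| `asymptomatic_bacteriuria` | asymptomatic bacteriuria | I8 |
| `nephrotic_syndrome` | nephrotic syndrome | B8 exclusion; CCI renal |
| `renal_failure` | moderate-severe renal disease | B8 exclusion; CCI renal |
| `dementia` | dementia | D1, D14, D20, I1, K-section context |
| `delirium` | delirium | D14, I1 |
| `bpsd` | behavioural and psychological symptoms of dementia | D5, D9, D15, D21 |
| `bpsd_severe_refractory` | severe BPSD refractory to other treatment | D15 exclusion |
| `parkinsonism` | parkinsonism | D12, F1 |
| `drug_induced_parkinsonism` | drug-induced parkinsonism / EPS | D13, D23 |
| `lewy_body_dementia` | dementia with Lewy bodies | D12, F1, I1 |
| `epilepsy` | seizure disorder | D19 |
| `essential_tremor` | benign essential tremor | D22 |
| `depression` | major depression | D2 |
| `psychosis` | psychosis | D16 exclusion, D21 |
| `insomnia` | insomnia | D10, D11, D16, D25 |
| `narrow_angle_glaucoma` | narrow-angle glaucoma | D1, G3, I2 |
| `copd` | chronic obstructive pulmonary disease | G1, G2; CCI |
| `respiratory_failure` | acute or chronic respiratory failure | G4 |
| `dependent_ankle_edema` | dependent ankle edema | B8 |
| `gout` | gout | B9, H6 |
| `osteoarthritis` | osteoarthritis | H3, H5, H7, H9, L4 |
| `rheumatoid_arthritis` | rheumatoid arthritis | H4, H7; CCI connective tissue |
| `connective_tissue_disease` | connective tissue disease | CCI |
| `diabetes_type2` | type 2 diabetes mellitus | J1, J3; CCI |
| `diabetes_complicated` | diabetes with end-organ damage | CCI weight 2 |
| `frequent_hypoglycemia` | frequent hypoglycaemic episodes | J3 |
| `symptomatic_hypotension` | symptomatic hypotension | J4 |
| `breast_cancer` | breast cancer history | J5 |
| `cancer` | malignancy (non-metastatic) | CCI weight 2 |
| `metastatic_cancer` | metastatic solid tumour | CCI weight 6 |
| `intact_uterus` | intact uterus | J8 |
| `liver_disease_mild` | mild chronic liver disease | L6; CCI weight 1 |
| `liver_disease_severe` | moderate-severe liver disease | L6; CCI weight 3 |
| `hemiplegia` | hemiplegia | CCI weight 2 |
| `aids` | AIDS | CCI weight 6 |
| `allergy_pruritus` | allergy or pruritus | D24 |
| `mild_pain` | mild pain | L1 |
| `neuropathic_pain` | neuropathic pain | L5 exclusion |
| `non_neuropathic_pain` | non-neuropathic chronic pain | L5 |
| `frailty_limited_life_expectancy` | established frailty, life expectancy < 3 years | B16 |
| `antihypertensive_intolerance` | intolerance of / failure on other antihypertensive classes | B11 exclusion |
| `xanthine_oxidase_contraindicated` | contraindication to xanthine-oxidase inhibitors | H6 exclusion |
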