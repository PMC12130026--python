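item	weight	conditions
myocardial_infarction	1	mi_history
congestive_heart_failure	1	heart_failure;heart_failure_preserved_ef;heart_failure_nyha_3_4
peripheral_vascular_disease	1	peripheral_vascular_disease;aortic_aneurysm
cerebrovascular_disease	1	stroke;cerebrovascular_disease
dementia	1	dementia;lewy_body_dementia
chronic_pulmonary_disease	1	copd
connective_tissue_disease	1	connective_tissue_disease;rheumatoid_arthritis
peptic_ulcer_disease	1	peptic_ulcer_disease
mild_liver_disease	1	liver_disease_mild
diabetes	1	diabetes_type2
hemiplegia	2	hemiplegia
moderate_severe_renal_disease	2	renal_failure;nephrotic_syndrome
diabetes_end_organ_damage	2	diabetes_complicated
any_tumor	2	cancer;breast_cancer
moderate_severe_liver_disease	3	liver_disease_severe
metastatic_solid_tumor	6	metastatic_cancer
aids	6	aids
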