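code	name	tags
B01AC06	acetylsalicylic acid	aspirin;antiplatelet
B01AC04	clopidogrel	antiplatelet
B01AC05	ticlopidine	antiplatelet;ticlopidine
B01AA03	warfarin	vitamin_k_antagonist;anticoagulant
B01AE07	dabigatran	direct_thrombin_inhibitor;anticoagulant
B01AF01	rivaroxaban	factor_xa_inhibitor;anticoagulant
B01AF02	apixaban	factor_xa_inhibitor;anticoagulant
B01AF03	edoxaban	factor_xa_inhibitor;anticoagulant
B01AB05	enoxaparin	heparin
M01AB05	diclofenac	nsaid;nsaid_nonselective
M01AE01	ibuprofen	nsaid;nsaid_nonselective
M01AE02	naproxen	nsaid;nsaid_nonselective
M01AH01	celecoxib	nsaid;cox2_selective
N06AB06	sertraline	ssri;antidepressant
N06AB04	citalopram	ssri;antidepressant
N06AB10	escitalopram	ssri;antidepressant
N06AX16	venlafaxine	snri;antidepressant
N06AX21	duloxetine	snri;antidepressant
N06AA09	amitriptyline	tca;antidepressant;anticholinergic;qtc_prolonging
N06AA04	clomipramine	tca;antidepressant;anticholinergic;qtc_prolonging
N03AE01	clonazepam	benzodiazepine;antiepileptic
N05BA01	diazepam	benzodiazepine
N05BA06	lorazepam	benzodiazepine
N05CF01	zopiclone	z_drug
N05CF02	zolpidem	z_drug
N05AX08	risperidone	antipsychotic
N05AD01	haloperidol	antipsychotic;qtc_prolonging
N05AH02	clozapine	antipsychotic;antipsychotic_anticholinergic;anticholinergic
N05AH03	olanzapine	antipsychotic;antipsychotic_anticholinergic;anticholinergic
N05AH04	quetiapine	antipsychotic
N05AA01	chlorpromazine	antipsychotic;phenothiazine;antipsychotic_anticholinergic;anticholinergic;qtc_prolonging
N05AB04	prochlorperazine	phenothiazine;metoclopramide_prochlorperazine
A03FA01	metoclopramide	metoclopramide_prochlorperazine
D04AA16	pheniramine	first_gen_antihistamine;anticholinergic
R06AB04	chlorphenamine	first_gen_antihistamine;anticholinergic
R06AD02	promethazine	first_gen_antihistamine;phenothiazine;anticholinergic
R06AE07	cetirizine	second_gen_antihistamine
R06AX13	loratadine	second_gen_antihistamine
C07AB03	atenolol	beta_blocker
C07AB07	bisoprolol	beta_blocker
C07AB02	metoprolol	beta_blocker
C07AG02	carvedilol	beta_blocker;beta_blocker_nonselective;p_gp_inhibitor
C07AA05	propranolol	beta_blocker;beta_blocker_nonselective
C08DA01	verapamil	verapamil_diltiazem;p_gp_inhibitor;constipating
C08DB01	diltiazem	verapamil_diltiazem
C08CA01	amlodipine	calcium_channel_blocker
C01AA05	digoxin	digoxin;qtc_prolonging
C01BD01	amiodarone	amiodarone;qtc_prolonging;p_gp_inhibitor
C03CA01	furosemide	loop_diuretic
C03CA04	torasemide	loop_diuretic
C03AA03	hydrochlorothiazide	thiazide
C03DA01	spironolactone	aldosterone_antagonist
C09AA03	lisinopril	ace_inhibitor
C09AA05	ramipril	ace_inhibitor
C09CA01	losartan	arb
C02DB02	hydralazine	vasodilator
C01DA02	glyceryl trinitrate	nitrate;vasodilator
C02AB01	methyldopa	central_antihypertensive
C02AC01	clonidine	central_antihypertensive
C02CA04	doxazosin	alpha1_blocker
G04CA02	tamsulosin	alpha1_blocker
G04CA04	silodosin	alpha1_blocker_silodosin
C10AA05	atorvastatin	statin
C10AA01	simvastatin	statin
G04BE03	sildenafil	pde5_inhibitor
G04BD12	mirabegron	mirabegron;qtc_prolonging
H02AB09	hydrocortisone	systemic_corticosteroid
H02AB06	prednisolone	systemic_corticosteroid
R03BA02	budesonide inhaled	inhaled_corticosteroid
R03AC02	salbutamol	inhaled_beta_agonist
R03BB04	tiotropium	lama
R03DA04	theophylline	theophylline
A02BC01	omeprazole	ppi
A02BA03	famotidine	h2_antagonist
B03AA07	ferrous sulfate	oral_iron;constipating
A06AB06	senna	laxative
N02AX02	tramadol	opioid;opioid_strong;constipating
N02AA01	morphine	opioid;opioid_strong;constipating
N02AB03	fentanyl	opioid;opioid_strong;opioid_long_acting;constipating
R05DA04	codeine	opioid;constipating
A10BB12	glimepiride	sulfonylurea;sulfonylurea_long_acting
A10BB01	glibenclamide	sulfonylurea;sulfonylurea_long_acting
A10BB09	gliclazide	sulfonylurea
A10BG03	pioglitazone	thiazolidinedione
A10BK03	empagliflozin	sglt2_inhibitor
A10BA02	metformin	metformin
A10AB01	insulin (human)
H03AA01	levothyroxine	levothyroxine
G03CA03	estradiol	systemic_estrogen
G03DA04	progesterone	progestogen
L02AB01	megestrol	megestrol;progestogen
H01BA02	desmopressin	vasopressin_analog
N04AA04	procyclidine	antiparkinson_anticholinergic;anticholinergic
N04AA01	trihexyphenidyl	antiparkinson_anticholinergic;anticholinergic
N04BA02	levodopa and decarboxylase inhibitor	levodopa_dopamine_agonist
N06DA02	donepezil	acetylcholinesterase_inhibitor
N06DX01	memantine	memantine
N06BX03	piracetam	nootropic
N03AF01	carbamazepine	antiepileptic
N03AG01	valproic acid	antiepileptic
N03AX14	levetiracetam	antiepileptic
N02BF01	gabapentin	gabapentinoid;antiepileptic
N02BF02	pregabalin	gabapentinoid;antiepileptic
G04BD04	oxybutynin	urological_antimuscarinic;anticholinergic
G04BD07	tolterodine	urological_antimuscarinic;anticholinergic
M04AC01	colchicine	colchicine
M04AA01	allopurinol	xanthine_oxidase_inhibitor
M05BA04	alendronic acid	bisphosphonate
J01XE01	nitrofurantoin	nitrofurantoin;antibiotic
L04AX03	methotrexate	methotrexate
J01CA04	amoxicillin	antibiotic
J01FA09	clarithromycin	antibiotic;macrolide;qtc_prolonging;p_gp_inhibitor
J01MA02	ciprofloxacin	antibiotic;quinolone;qtc_prolonging
N02BE01	paracetamol	paracetamol
N05AN01	lithium	lithium;qtc_prolonging
N01BB02	lidocaine	lidocaine_patch
A04AA01	ondansetron	qtc_prolonging
A11BA01	multivitamins
A11CC05	colecalciferol
A11GA01	ascorbic acid
A11HA02	pyridoxine
A12AA04	calcium carbonate
A12BA01	potassium chloride
B03BB01	folic acid
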