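# pimscreen

Screening of **potentially inappropriate medications (PIMs)** in hospitalized
older adults with the **STOPP version-3 criteria**, plus the statistics a
pharmacoepidemiological screening study runs on top of the flags.

Prescribing for patients aged 60+ is complicated by multimorbidity and
polypharmacy; explicit criteria such as STOPP ("Screening Tool of Older
Persons' Prescriptions") flag prescriptions whose risks likely outweigh
their benefits — an NSAID in renal impairment, a first-generation
antihistamine for allergy, long-term aspirin above 100 mg/day.  This package
is for pharmacists, geriatricians and pharmacoepidemiologists who want those
133 rules as a deterministic, testable rule engine rather than a manual
chart review, together with the downstream analysis: prevalence, per-system
and per-drug tallies, Charlson comorbidity scoring, crude odds ratios from
2×2 tables, a p < 0.25 bivariate screen, and multivariable logistic
regression for adjusted odds ratios.

## What's inside

| Module | Role |
|---|---|
| `pimscreen.cohort` | patient/medication domain types, JSON + two-table CSV readers/writers, total validation |
| `pimscreen.drugs` | packaged ATC level-5 catalog → pharmacological class tags (`classify`, `anticholinergic_burden`) |
| `pimscreen.engine` / `pimscreen.rules` | all 133 STOPP v3 predicates, tri-state evaluation, `screen_cohort`, `tally` |
| `pimscreen.comorbidity` | original Charlson index weights, severity bands, multimorbidity trichotomy |
| `pimscreen.analytics` | prevalence, Woolf-CI crude ORs, chi-square bivariate screen, ML logistic aORs, sample size |
| `pimscreen.simulate` | synthetic cohorts with published marginals; planted-effect exposure for parameter recovery |
| `pimscreen.fixture` | deterministic 450-patient reference cohort reproducing the published screening margins |
| `pimscreen.cli` | `pimscreen screen | summarize | regress | simulate | sample-size` |

The statistics, in the field's notation: crude OR = (a·d)/(b·c) with Woolf
95% CI exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); adjusted OR = exp(β̂)
from a maximum-likelihood logistic fit dummy-coded against the reference
levels (female, 60–64 years, 1–4 medications, no comorbidity); sample size
n₀ = z²p(1−p)/d², inflated by the attrition fraction.

## Worked example

```python
from pimscreen import (PatientRecord, LabPanel, MedicationOrder,
                       screen_patient, cci_score)

patient = PatientRecord(
    patient_id="W-001", age_years=74, sex="male",
    conditions={"coronary_artery_disease", "allergy_pruritus"},
    labs=LabPanel(egfr=42.0),
    medications=(
        MedicationOrder("M01AB05", name="diclofenac", daily_dose=100,
                        duration_days=30),
        MedicationOrder("D04AA16", name="pheniramine", daily_dose=25,
                        duration_days=7),
    ),
)
for flag in screen_patient(patient):
    print(flag.criterion_id, flag.atc_codes)
print("CCI:", cci_score(patient.conditions))
```

prints

```
D24 ('D04AA16',)
E4 ('M01AB05',)
CCI: CCIResult(score=0, band='none', contributing_conditions=())
```

— the first-generation antihistamine is flagged as first-line allergy
treatment and the NSAID under the renal rule (eGFR 42 < 50 mL/min/1.73 m²);
coronary artery disease carries no Charlson weight, so the index is 0.

Screening the packaged reference cohort end to end
(`python analysis/01_screen_reference_cohort.py`):

```
screened 450 patients: 388 PIM instances
patients with >=1 PIM: 255 (56.7%)
per-system: {... 'cardiovascular': 71, 'central_nervous_system': 71,
             'coagulation': 52, ...}
```

i.e. a 56.7% PIM prevalence, with cardiovascular and central-nervous-system
rules contributing 71 instances each (18.3% of 388) and coagulation 52
(13.4%).  The top inappropriately prescribed drug is acetylsalicylic acid
(B01AC06) with 70 instances (18%), followed by pheniramine (44, 11%).

The numbered scripts under `analysis/` run the full study pipeline over the
reference cohort: screening and tallies (`01`), demographics and top-drug
attribution (`02`), crude odds ratios, the bivariate screen and the
sample-size check (`03`), and regression parameter recovery (`04`).  Outputs
land in `results/`.

## Command line

```bash
pimscreen simulate --n 450 --seed 7 --out cohort.json
pimscreen screen cohort.json --out results/
pimscreen regress cohort.json --out results/
pimscreen simulate --fixture reference --out reference.json
pimscreen sample-size --p 0.64 --d 0.05 --attrition 0.2   # -> 425
```

Exit codes: 0 success, 2 validation failure, 3 convergence/feasibility
failure.  Every run writes its resolved configuration next to its outputs.

## Design notes

See `docs/methods.md` for the screening model (tri-state evaluation,
instance counting, temporal and first-line conventions, dose thresholds),
the statistics, the deterministic reference-cohort construction, and the
synthetic generator's assumptions and limitations;
`docs/condition_vocabulary.md` maps every condition code to the clinical
state it encodes.
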