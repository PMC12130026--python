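# Methods

This note documents the models, rules and numerical choices behind
`pimscreen`, and what its synthetic data do and do not establish.

## Screening model

The package evaluates the 133 explicit prescribing rules of the STOPP
version-3 screening tool ("Screening Tool of Older Persons' Prescriptions")
against structured records of hospitalized adults aged 60 and above.  Each
rule is a declarative predicate over:

* **drug classes** — ATC level-5 codes resolved to pharmacological class
  tags through a packaged, versioned catalog (a curated ATC subset; no
  network lookup, so classification is deterministic forever);
* **conditions** — a closed, versioned vocabulary of clinical states
  (`docs/condition_vocabulary.md`); a condition is present iff recorded;
* **laboratory values** — optional numeric fields with fixed units
  (eGFR in mL/min/1.73 m², electrolytes in mmol/L, QTc in msec, blood gases
  in kPa, …).  Readers reject other units rather than converting: silent
  unit conversion is the classic screening bug, so unit mismatch is a
  validation error;
* **order attributes** — daily dose, route, PRN flag, and duration of
  continuous use.

### Tri-state evaluation

A criterion evaluates to *triggered*, *not triggered*, or *not evaluable*.
The third state arises when the drug clause is satisfied but a required
laboratory value is missing (e.g. an NSAID user with no recorded eGFR for
the renal rule).  Not-evaluable outcomes are excluded from all tallies, so
"no data" is never conflated with "appropriate prescribing".  Condition
absence, by contrast, is interpreted as absence of the disease (the
vocabulary is closed), not as missing data.

One deliberate inversion: the potassium-monitoring rule (aldosterone
antagonist plus a potassium-conserving drug *without monitoring*) treats the
absence of a serum-potassium value as the trigger itself — the missing
measurement is exactly the unmonitored state the rule penalizes.

### Instance counting

One flag is one (patient, criterion, triggering drug set) instance.  Several
distinct drugs independently satisfying one criterion yield several
instances; a combination rule (e.g. NSAID + anticoagulant) yields one
instance whose subject is the drug the rule targets, with the partner drug
recorded in the same set.  Per-drug tallies attribute each instance to its
subject drug.  Overlapping criteria fired by one prescription are all
reported; no de-duplication is applied.

### Conventions shared across rules

* Temporal clauses are read calendar-literally from the recorded duration of
  continuous use: "> 3 months" = > 90 days, ">= 4 weeks" = >= 28 days,
  ">= 2 weeks" = >= 14 days, "> 8 weeks" = > 56 days, "> 12 weeks" = > 84
  days, "> 6 months" = > 180 days; an unqualified "long-term" means > 90
  days.
* "First-line" and "monotherapy" clauses are decided from the absence of the
  alternative drug class on the current medication list.  Prescription
  *sequence* history is not modelled; this is a documented limitation, not
  an approximation the data could refine.
* Duplicate-class (A3) and anticholinergic-burden (M1) rules count regular
  orders only, following the rule text's "as distinct from PRN use"; all
  other rules consider any order.
* Sex-specific QTc thresholds (450 msec in males, 470 in females) are read
  from the recorded sex.
* The renal NSAID rule includes low-dose aspirin (pharmacologically an NSAID
  with the same renal prostaglandin-mediated effect), while the
  anti-inflammatory duplicate/gastro/musculoskeletal NSAID rules use an
  anti-inflammatory tag that excludes the antiplatelet aspirin code.  This
  is also what makes the published per-drug attribution arithmetically
  attainable (see "Reference cohort" below).
* "Systemic" versus "topical" is decided by the order's route, never by the
  ATC code.
* The anticholinergic-potency tag list follows the drugs enumerated in the
  rule texts; no external potency scale is assumed, because none is
  specified by the screening tool.

### Dose thresholds carried by specific rules

aspirin > 100 mg/day; digoxin >= 125 µg/day (renal rule); citalopram
> 20 mg/day and escitalopram > 10 mg/day (QTc list); oral iron > 600 mg/day
of salt (1800 for gluconate); PPI full therapeutic dose >= 20 mg/day
omeprazole-equivalent; paracetamol >= 3 g/day.  TSH "elevated but < 10 mU/L"
is read as 4.5 < TSH < 10 with normal free T4.

## Comorbidity scoring

The Charlson Comorbidity Index uses the original, un-age-adjusted weights
(17 groups weighted 1/2/3/6); within the graded pairs (diabetes vs. diabetes
with end-organ damage, mild vs. moderate-severe liver disease, any tumour
vs. metastatic tumour) only the more severe member scores.  Severity bands:
none (0), mild (1-2), moderate (3-4), severe (>= 5).  The un-adjusted index
is used because the stated bands read as raw Charlson scores; no age points
appear anywhere in the study definitions.

The separate none/comorbidity/multimorbidity trichotomy counts qualifying
*chronic* conditions (diabetes, cancer, cerebrovascular disease,
hypertension, ischaemic heart disease, plus the Charlson
cardio-/cerebrovascular block); graded variants of one disease count once.
The source text contains a sentence folding zero-comorbidity patients into
the severe band; the cross-tabulation that carries a separate "no
comorbidity" reference row contradicts it, and the latter reading is
implemented.

## Statistics

* **Prevalence** — patients with >= 1 instance over cohort size; displayed
  half-up to 1 decimal.  255/450 computes to 56.67% and displays as 56.7%;
  the reference report prints 56.6% (truncation), a documented 0.1-point
  discrepancy.
* **Crude odds ratios** — (a·d)/(b·c) with Woolf log-normal 95% CIs,
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), and a two-sided Wald p.  A zero cell
  is an error unless the Haldane-Anscombe 0.5 correction is explicitly
  enabled.  The Woolf intervals reproduce the published medication and
  comorbidity CIs to ±0.01; the published male-row upper bound (1.77) is
  not reproducible from the printed counts (Woolf gives 1.68) and the point
  estimate is treated as the comparable quantity for that row.
* **Bivariate screen** — Pearson chi-square on the k×2 exposure-by-outcome
  table without continuity correction (the default line of the statistical
  package the study used), at the p < 0.25 inclusion threshold; Fisher's
  exact test is the documented fallback when an expected cell falls below 1.
* **Adjusted odds ratios** — maximum-likelihood logistic regression
  (Newton iterations, tolerance 1e-8, 100 iterations max) with dummy coding
  against the study reference levels (female; 60-64 years; 1-4 medications;
  no comorbidity); aOR = exp(β) with Wald CIs; α = 0.05.  Separation or
  non-convergence raises a diagnostic error; nothing is reported silently.
* **Sample size** — single-proportion formula n₀ = z²p(1−p)/d², inflated by
  the anticipated attrition fraction as n₀ × (1 + a) and rounded *up*.
  With p = 0.64, d = 0.05, z = 1.96, a = 0.20 this gives ⌈424.85⌉ = 425,
  matching the study target; the alternative inflation n₀/(1−a) = 442.5
  does not and is not used.
* **Display** — ORs half-up to 2 decimals, percentages to 1; interquartile
  ranges printed as "median (Q3-Q1)" mirroring the reference report's
  convention.

## Reference cohort (deterministic fixture)

Patient-level data behind the published tallies were never deposited, so the
package reconstructs a 450-patient cohort *by direct placement* from the
published margins: per-criterion instance counts (summing to 388), the
1..5-instances-per-patient distribution (163/62/22/5/3 over 255 flagged
patients), the sex, age-band and medication-band marginals, the published
PIM × sex, PIM × age and PIM × medication-band cross-tabulations, and the
leading per-drug attributions (acetylsalicylic acid 70, pheniramine 44,
hydrocortisone 28, hydralazine 22, tramadol 23).

Each instance is realised as a "bundle" — a minimal medication + condition
+ laboratory constellation firing exactly one criterion, with laboratory
values placed just past the rule threshold so triggers are unambiguous.
Bundles are packed onto patients greedily, and every placement (and every
padding medication added afterwards to reach the medication-band quotas) is
verified by re-screening the trial patient, so no combination can silently
create or suppress an instance.  The assignment of instances to multi-PIM
patients is one valid arrangement among many — the published margins do not
identify which patients carried which combinations.

Two published tables are *not* jointly satisfiable and are resolved in
favour of the per-criterion counts: (i) several lower rows of the top-20
drug attribution exceed any attribution the criterion counts allow
(e.g. furosemide 27 against at most 21 loop-diuretic instances); the top
rows are reproduced exactly, lower rows best-effort.  (ii) The published
PIM × comorbidity cross-tabulation is not enforced on the flagged side,
because the instance bundles themselves dictate chronic conditions; the
unflagged side carries chronic conditions matching the published margins,
and comorbidity odds ratios are computed from the published counts directly
(printed tables are valid inputs to the odds-ratio stage).

## Synthetic generator

`CohortSpec`/`generate` sample fully valid random cohorts: sex (55.3% male),
the six age bands (114/135/95/35/33/38 over 450), medication bands
(91/309/50), condition prevalences (hypertension 49.6%, diabetes 33.8% as
published; the remaining defaults are plausible tertiary-hospital rates
chosen once: CAD 20%, heart failure 10%, COPD 10%, recurrent falls 10%, …),
and per-criterion trigger rates defaulting to the published instance counts
over 450.  Trigger constellations attach their required conditions, so the
base condition-sampling probabilities are deflated to keep realized marginal
prevalences at spec values.  Covariates are sampled *independently*: the
real cohort's joint correlation structure was never reported and is not
claimed.  Consequences: screened totals on sampled cohorts are close to,
but not exactly, n × rate (interactions can suppress or add instances), and
passing tests on synthetic cohorts establish engine correctness, not
real-world prevalence estimates.

For regression recovery, PIM exposure is *planted*: drawn from a logistic
model on the four analysis covariates with log-odds equal to the published
adjusted ORs (male 1.31; ages 1.35/1.38/1.76/1.54/0.77; medications
2.89/8.42; comorbidity 3.12/2.11), with the intercept calibrated by
root-finding so the marginal exposure prevalence is 56.6% under the
covariate distribution (closed-form enumeration over the 108 covariate
cells; brentq on [-20, 20]).  Point recovery is demonstrated on one large
cohort (n = 100,000; maximum likelihood is consistent, so the fit lands
within a few percent of the planted values), and interval calibration by
~95% Wald CI coverage over 300-500 replicates at the study size (n = 450).
The study-size replicates are not used for point recovery because
small-sample ML bias in the sparse >= 10-medications band (≈ 50 patients)
inflates exp(mean β) by up to ~10%.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeded from the
  spec or CLI; identical seeds give byte-identical serialized cohorts.
* The reference fixture's demographic interleaving uses a fixed build seed;
  the fixture is version-pinned, exact, and cached per process.
* 2×2 tables with any zero cell raise unless continuity correction is
  explicitly requested; k×2 screens with an expected cell < 1 fall back to
  the exact test (2×2) or demand level collapsing (k > 2).
* `sample_size` floors at 1 as the precision grows without bound.
* Cohort validation is total and typed: age below 60, an empty medication
  list, an unknown condition token, a malformed ATC code, an unknown dose
  unit or a non-positive laboratory value each raise an error naming the
  record and field.

## Known limitations

* "First-line" semantics are cross-sectional (see above).
* The condition vocabulary is closed; real EHR ingestion (HL7/FHIR), free
  text, and drug-name → ATC resolution are out of scope.
* The ATC catalog is a curated subset sufficient for the 133 rules and the
  packaged analyses; unknown codes classify to the empty tag set with a
  warning rather than an error.
* The comorbidity side of the reference fixture's cross-tabulation is
  best-effort (see "Reference cohort").
* Monotonicity of screening under medication-list growth holds for inert
  additions; rules with monotherapy/first-line/absence clauses are by
  design non-monotone in the medication list.
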