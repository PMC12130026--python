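"""Deterministic reference cohort.

Patient-level data for the reference study were never deposited; only margins
were published (per-criterion instance counts, the per-patient PIM
distribution, demographic bands and the leading per-drug attributions).
This module constructs, by direct placement rather than sampling, one
450-patient cohort whose screening output reproduces those margins exactly:

* 388 PIM instances with the published per-criterion and per-system counts;
* 255 flagged patients distributed 163/62/22/5/3 over 1..5 PIMs;
* the leading drug attributions (acetylsalicylic acid 70, pheniramine 44,
  hydrocortisone 28, hydralazine 22, tramadol 23 instances);
* the published sex, age-band and medication-band marginals.

Construction works from "bundles": each bundle is a minimal medication +
condition + laboratory constellation firing exactly one criterion instance.
Bundles are packed onto patients greedily, and every placement is verified by
actually screening the trial patient, so no combination can silently create
or suppress an instance.  The assignment of instances to multi-PIM patients
is one valid arrangement among many, which is all the published margins
constrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .cohort import Cohort, LabPanel, MedicationOrder, PatientRecord
from .engine import screen_patient
from .recipes import med
from . import reference_data as ref

_BUILD_SEED = 20240317  # fixes the demographic interleaving; not a dial

#: Medications that appear in no predicate: safe padding to reach the
#: published medication-count bands (re-verified by screening anyway).
_INERT_MEDS = [
    med("A11BA01", 1, days=30),
    med("A12AA04", 500, days=30),
    med("A11CC05", 20, unit="ug", days=30),
    med("B03BB01", 5, days=30),
    med("A11GA01", 500, days=30),
    med("A11HA02", 25, days=30),
    med("A12BA01", 600, days=30),
    med("A10AB01", 20, route="parenteral", days=30),
    med("N02BE01", 1000, days=10),
    med("B03AA07", 200, days=30),
]


@dataclass(frozen=True)
class Bundle:
    criterion_id: str
    meds: tuple[MedicationOrder, ...]
    conditions: frozenset[str] = frozenset()
    labs: dict = field(default_factory=dict)
    subject: str = ""            # ATC code the instance is attributed to
    sex: Optional[str] = None
    age_min: Optional[int] = None

    @property
    def expected(self) -> tuple[str, str]:
        return (self.criterion_id, self.subject)


def _b(cid, meds, conds=(), labs=None, subject=None, sex=None, age_min=None):
    meds = tuple(meds)
    return Bundle(
        criterion_id=cid, meds=meds, conditions=frozenset(conds),
        labs=dict(labs or {}), subject=subject or meds[0].atc_code,
        sex=sex, age_min=age_min,
    )


def bundle_pool() -> list[Bundle]:
    """The 388 instance bundles, one per published PIM instance."""
    pool: list[Bundle] = []

    def add(n: int, *args, **kw):
        for _ in range(n):
            pool.append(_b(*args, **kw))

    # A — indication
    add(3, "A1", [med("B01AB05", 40, route="parenteral", days=5,
                      indication="no_indication")])
    add(1, "A3", [med("N06AB06", 50, days=30), med("N06AB10", 10, days=30)])
    add(1, "A3", [med("C03CA01", 40, days=30), med("C03CA04", 10, days=30)])
    add(1, "A3", [med("C09AA03", 10, days=30), med("C09AA05", 5, days=30)])
    # B — cardiovascular
    add(2, "B2", [med("C08DA01", 120, days=30)], ["heart_failure_nyha_3_4"])
    add(2, "B4", [med("C07AB02", 50, days=30)], ["bradycardia"])
    add(6, "B5", [med("C07AB03", 50, days=60)], ["hypertension"])
    add(5, "B5", [med("C07AB07", 5, days=60)], ["hypertension"])
    add(7, "B5", [med("C07AG02", 12.5, days=60)], ["hypertension"])
    add(5, "B5", [med("C07AB02", 50, days=60)], ["hypertension"])
    add(1, "B6", [med("C01BD01", 200, days=30)], ["supraventricular_tachyarrhythmia"])
    add(12, "B7", [med("C03CA01", 40, days=60)], ["hypertension"])
    add(9, "B8", [med("C03CA01", 40, days=30)], ["dependent_ankle_edema"])
    add(1, "B13", [med("C03DA01", 25, days=30), med("C09AA03", 10, days=30)])
    add(6, "B15", [med("J01FA09", 500, days=5)], labs={"qtc_ms": 480})
    add(1, "B16", [med("C10AA05", 20, days=120)],
        ["frailty_limited_life_expectancy"], age_min=85)
    add(1, "B17", [med("M01AE01", 1200, days=120)], ["coronary_artery_disease"])
    add(2, "B18", [med("N05AX08", 2, days=120)], ["coronary_artery_disease"])
    add(2, "B19", [med("M01AE01", 1200, days=20), med("C03CA01", 40, days=30)],
        ["heart_failure"])
    add(2, "B19", [med("H02AB06", 10, days=20), med("C03CA01", 40, days=30)],
        ["heart_failure"])
    add(7, "B21", [med("C01AA05", 0.25, days=120)], ["atrial_fibrillation"])
    # C — coagulation
    add(5, "C1", [med("B01AC06", 150, days=120)], ["coronary_artery_disease"])
    add(4, "C2", [med("B01AC06", 75, days=30)],
        ["recent_bleeding", "coronary_artery_disease"])
    add(4, "C3", [med("B01AC06", 75, days=60), med("B01AC04", 75, days=60)],
        ["stroke"])
    add(2, "C4", [med("B01AC06", 75, days=60), med("B01AA03", 5, days=60)],
        ["atrial_fibrillation", "metallic_heart_valve"])
    add(13, "C5", [med("B01AC06", 75, days=60), med("B01AA03", 5, days=60)],
        ["coronary_artery_disease"])
    add(3, "C10", [med("M01AB05", 100, days=10), med("B01AA03", 5, days=60)])
    add(3, "C11", [med("B01AA03", 5, days=60)], ["atrial_fibrillation"])
    add(1, "C12", [med("N06AB06", 50, days=60), med("B01AA03", 5, days=60)],
        ["bleeding_history_major"])
    add(2, "C14", [med("B01AF01", 20, days=30), med("C08DA01", 120, days=30)])
    add(15, "C16", [med("B01AC06", 75, days=60)])
    # D — central nervous system
    add(4, "D7", [med("N06AB06", 50, days=30)], ["recent_bleeding"])
    add(5, "D8", [med("N03AE01", 0.5, days=35)])
    add(2, "D8", [med("N05BA01", 5, days=35)])
    add(1, "D9", [med("N03AE01", 0.5, days=10)], ["bpsd"])
    add(1, "D9", [med("N05BA06", 1, days=10)], ["bpsd"])
    add(4, "D10", [med("N03AE01", 0.5, days=15)], ["insomnia"])
    add(2, "D12", [med("N05AX08", 1, days=10)], ["parkinsonism"])
    add(7, "D13", [med("N04AA04", 7.5, days=30), med("N05AD01", 2, days=30)])
    add(1, "D14", [med("R06AD02", 25, days=10)], ["dementia"])
    add(44, "D24", [med("D04AA16", 25, days=7)], ["allergy_pruritus"])
    # E — renal
    add(24, "E4", [med("B01AC06", 75, days=60)], ["coronary_artery_disease"],
        labs={"egfr": 40})
    add(14, "E4", [med("M01AB05", 75, days=30)], labs={"egfr": 40})
    add(1, "E4", [med("M01AE01", 1200, days=30)], labs={"egfr": 40})
    add(1, "E6", [med("A10BA02", 1000, days=60)], ["diabetes_type2"],
        labs={"egfr": 25})
    # F — gastrointestinal
    add(5, "F2", [med("A02BC01", 20, days=70)], ["peptic_ulcer_disease"])
    add(3, "F6", [med("B01AC06", 75, days=30)],
        ["gave", "coronary_artery_disease"])
    # G — respiratory
    add(1, "G1", [med("R03DA04", 200, days=60)], ["copd"])
    add(28, "G2", [med("H02AB09", 100, route="parenteral", days=5)], ["copd"])
    add(1, "G2", [med("H02AB06", 30, days=10)], ["copd"])
    # H — musculoskeletal
    add(1, "H2", [med("M01AB05", 100, days=10)],
        labs={"systolic_bp": 180, "diastolic_bp": 95})
    # I — urogenital
    add(1, "I5", [med("G04CA02", 0.4, days=60)],
        ["orthostatic_hypotension", "syncope_history", "bph_luts"])
    add(5, "I8", [med("J01CA04", 1500, days=5)], ["asymptomatic_bacteriuria"])
    # J — endocrine
    add(8, "J1", [med("A10BB12", 2, days=60)], ["diabetes_type2"])
    add(4, "J1", [med("A10BB01", 5, days=60)], ["diabetes_type2"])
    add(6, "J2", [med("A10BG03", 15, days=60)], ["heart_failure"])
    add(1, "J4", [med("A10BK03", 10, days=30)], ["symptomatic_hypotension"])
    add(1, "J8", [med("G03CA03", 1, days=60)], ["intact_uterus"], sex="female")
    add(2, "J9", [med("H03AA01", 50, unit="ug", days=60)],
        labs={"tsh_mu_l": 7.0, "free_t4_status": "normal"})
    # K — falls risk
    add(3, "K1", [med("N05BA01", 5, days=10)], ["recurrent_falls"])
    add(3, "K1", [med("N05BA06", 1, days=10)], ["recurrent_falls"])
    add(2, "K2", [med("N05AX08", 1, days=10)], ["recurrent_falls"])
    add(3, "K2", [med("N05AD01", 1.5, days=10)], ["recurrent_falls"])
    add(22, "K3", [med("C02DB02", 75, days=30)],
        ["recurrent_falls", "orthostatic_hypotension"])
    add(5, "K3", [med("C01DA02", 5, days=30)],
        ["recurrent_falls", "orthostatic_hypotension"])
    add(4, "K5", [med("N03AG01", 500, days=60)], ["recurrent_falls"])
    add(3, "K5", [med("N03AF01", 400, days=60)], ["recurrent_falls"])
    add(2, "K6", [med("R06AB04", 4, days=7)], ["recurrent_falls"])
    add(1, "K7", [med("N02AX02", 100, days=10), med("A06AB06", 15, days=10)],
        ["recurrent_falls"])
    # L — analgesics
    add(6, "L1", [med("N02AX02", 100, days=5), med("A06AB06", 15, days=5)],
        ["mild_pain"])
    add(16, "L2", [med("N02AX02", 100, days=10)])
    add(5, "L5", [med("N02BF02", 150, days=30)], ["non_neuropathic_pain"])
    add(3, "L5", [med("N02BF01", 600, days=30)], ["non_neuropathic_pain"])
    # M — anticholinergic burden
    add(2, "M1", [med("N04AA04", 7.5, days=30), med("R06AD02", 25, days=30)])
    add(1, "M1", [med("N06AA09", 25, days=30), med("G04BD04", 5, days=30)])

    assert len(pool) == ref.TOTAL_PIM_INSTANCES
    return pool


def _assemble(bundles: list[Bundle], patient_id: str,
              age: int, sex: str) -> PatientRecord:
    meds: list[MedicationOrder] = []
    conditions: set[str] = set()
    labs: dict = {}
    for b in bundles:
        meds.extend(b.meds)
        conditions |= b.conditions
        labs.update(b.labs)
    return PatientRecord(
        patient_id=patient_id, age_years=age, sex=sex,
        conditions=frozenset(conditions), labs=LabPanel(**labs),
        medications=tuple(meds),
    )


def _compatible(bundles: list[Bundle], candidate: Bundle) -> bool:
    codes = {m.atc_code for b in bundles for m in b.meds}
    if codes & {m.atc_code for m in candidate.meds}:
        return False
    labs: dict = {}
    for b in bundles:
        labs.update(b.labs)
    for k, v in candidate.labs.items():
        if k in labs and labs[k] != v:
            return False
    sexes = {b.sex for b in bundles + [candidate] if b.sex}
    if len(sexes) > 1:
        return False
    return True


def _verify(bundles: list[Bundle]) -> bool:
    """Screen the trial patient; accept only if the flag multiset equals the
    union of the bundles' expected (criterion, subject) instances."""
    age = max([b.age_min or 70 for b in bundles])
    sex = next((b.sex for b in bundles if b.sex), "male")
    patient = _assemble(bundles, "TRIAL", age, sex)
    flags = screen_patient(patient)
    actual = sorted((f.criterion_id, f.subject_code) for f in flags)
    expected = sorted(b.expected for b in bundles)
    return actual == expected


@lru_cache(maxsize=1)
def generate_reference_fixture() -> Cohort:
    """Build (once per process) the deterministic 450-patient fixture."""
    rng = np.random.default_rng(_BUILD_SEED)
    pool = bundle_pool()
    # scarce criteria first so multi-PIM patients draw distinct rare bundles
    counts: dict[str, int] = {}
    for b in pool:
        counts[b.criterion_id] = counts.get(b.criterion_id, 0) + 1
    pool.sort(key=lambda b: (counts[b.criterion_id], b.criterion_id, b.subject))

    arities = ([5] * ref.PIMS_PER_PATIENT[5] + [4] * ref.PIMS_PER_PATIENT[4]
               + [3] * ref.PIMS_PER_PATIENT[3] + [2] * ref.PIMS_PER_PATIENT[2]
               + [1] * ref.PIMS_PER_PATIENT[1])
    assigned: list[list[Bundle]] = []
    remaining = list(pool)
    for arity in arities:
        chosen: list[Bundle] = []
        for b in list(remaining):
            if len(chosen) == arity:
                break
            if not _compatible(chosen, b):
                continue
            trial = chosen + [b]
            if _verify(trial):
                chosen = trial
                remaining.remove(b)
        if len(chosen) != arity:
            raise RuntimeError(
                f"fixture packing failed: wanted {arity} compatible bundles, "
                f"found {len(chosen)} with {len(remaining)} remaining"
            )
        assigned.append(chosen)
    if remaining:
        raise RuntimeError(f"fixture packing left {len(remaining)} bundles unplaced")

    # demographics: realize the published PIM x sex, PIM x age-band and
    # PIM x medication-band cross-tabulations exactly ----------------------
    n_flagged = len(assigned)
    n_total = ref.COHORT_N
    flagged_idx = list(range(n_flagged))
    unflagged_idx = list(range(n_flagged, n_total))

    kx2 = ref.KX2_TABLES
    sex_quota = {
        True: {"female": kx2["sex"][0][0], "male": kx2["sex"][1][0]},
        False: {"female": kx2["sex"][0][1], "male": kx2["sex"][1][1]},
    }
    age_bands = ["60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
    age_quota = {
        True: {b: kx2["age_band"][j][0] for j, b in enumerate(age_bands)},
        False: {b: kx2["age_band"][j][1] for j, b in enumerate(age_bands)},
    }

    sex_req = [next((b.sex for b in bs if b.sex), None) for bs in assigned]
    age_req = [max((b.age_min or 0 for b in bs), default=0) for bs in assigned]

    def draw_labels(quota: dict[str, int], reserved: list[str]) -> list[str]:
        labels = [k for k, n in quota.items() for _ in range(n)]
        for r in reserved:
            labels.remove(r)
        rng.shuffle(labels)
        return labels

    # in-band ages decline in frequency with age (younger-old predominate),
    # giving a cohort median/IQR close to the published 67 (74-64)
    def age_pool(band: str, k: int) -> list[int]:
        if band == "85+":
            values, weights = list(range(85, 91)), [.40, .25, .15, .10, .05, .05]
        else:
            lo = int(band.split("-")[0])
            values, weights = list(range(lo, lo + 5)), [.45, .25, .15, .10, .05]
        counts = [int(w * k) for w in weights]
        while sum(counts) < k:
            counts[int(np.argmax(np.asarray(weights) - np.asarray(counts) / k))] += 1
        pool = [v for v, c in zip(values, counts) for _ in range(c)]
        rng.shuffle(pool)
        return pool

    band_ages = {b: age_pool(b, k) for b, k in ref.AGE_BAND_COUNTS.items()}

    sexes = [""] * n_total
    ages = [0] * n_total
    f_sex = draw_labels(sex_quota[True], [s for s in sex_req if s])
    f_age = draw_labels(age_quota[True], ["85+" for a in age_req if a >= 85])
    si = bi = 0
    for i in flagged_idx:
        if sex_req[i]:
            sexes[i] = sex_req[i]
        else:
            sexes[i] = f_sex[si]
            si += 1
        band = "85+" if age_req[i] >= 85 else f_age[bi]
        if age_req[i] < 85:
            bi += 1
        ages[i] = band_ages[band].pop()
    u_sex = draw_labels(sex_quota[False], [])
    u_age = draw_labels(age_quota[False], [])
    for j, i in enumerate(unflagged_idx):
        sexes[i] = u_sex[j]
        ages[i] = band_ages[u_age[j]].pop()

    # unflagged patients carry chronic conditions per the published
    # comorbidity margins (none 85 / one 52 / two 58); inert drugs only
    u_conditions = ([frozenset()] * kx2["comorbidity"][0][1]
                    + [frozenset({"hypertension"})] * kx2["comorbidity"][1][1]
                    + [frozenset({"hypertension", "diabetes_type2"})]
                    * kx2["comorbidity"][2][1])
    u_perm = rng.permutation(len(u_conditions))

    patients: list[PatientRecord] = []
    for i, bs in enumerate(assigned):
        patients.append(_assemble(bs, f"P{i + 1:04d}", ages[i], sexes[i]))
    for j, i in enumerate(unflagged_idx):
        patients.append(PatientRecord(
            patient_id=f"P{i + 1:04d}", age_years=ages[i], sex=sexes[i],
            conditions=u_conditions[u_perm[j]], labs=LabPanel(),
            medications=(_INERT_MEDS[0], _INERT_MEDS[1]),
        ))

    # pad medication lists so the PIM x band cross-tab is exact:
    # flagged 30/184/41 and unflagged 61/125/9 over low/mid/high.
    # Per-band target counts are spread (rather than pinned to the band
    # floor) so the medication distribution has a realistic median/IQR.
    band_members: dict[str, list[int]] = {"low": [], "mid": [], "high": []}
    for flagged, idx in ((True, flagged_idx), (False, unflagged_idx)):
        quota = {b: kx2["med_band"][j][0 if flagged else 1]
                 for j, b in enumerate(["low", "mid", "high"])}
        order = sorted(idx, key=lambda i: (-len(patients[i].medications), i))
        for rank, i in enumerate(order):
            if rank < quota["high"]:
                band_members["high"].append(i)
            elif rank < quota["high"] + quota["mid"]:
                band_members["mid"].append(i)
            else:
                band_members["low"].append(i)

    def spread(values_counts: list[tuple[int, int]]) -> list[int]:
        return [v for v, c in values_counts for _ in range(c)]

    band_targets = {
        "low": spread([(4, 20), (3, 30), (2, 41)]),
        "mid": spread([(9, 31), (8, 40), (7, 49), (6, 87), (5, 102)]),
        "high": spread([(12, 10), (11, 15), (10, 25)]),
    }
    targets: dict[int, int] = {}
    for band, members in band_members.items():
        # largest targets go to the patients with the most natural orders
        members = sorted(members, key=lambda i: (-len(patients[i].medications), i))
        tlist = sorted(band_targets[band][:len(members)], reverse=True)
        for i, t in zip(members, tlist):
            targets[i] = t
    for i in range(n_total):
        p = patients[i]
        want = targets[i]
        if len(p.medications) >= want:
            continue
        baseline = sorted((f.criterion_id, f.subject_code)
                          for f in screen_patient(p))
        meds = list(p.medications)
        have = {m.atc_code for m in meds}
        for candidate in _INERT_MEDS:
            if len(meds) >= want:
                break
            if candidate.atc_code in have:
                continue
            trial = PatientRecord(
                patient_id=p.patient_id, age_years=p.age_years, sex=p.sex,
                conditions=p.conditions, labs=p.labs,
                medications=tuple(meds) + (candidate,),
            )
            if sorted((f.criterion_id, f.subject_code)
                      for f in screen_patient(trial)) == baseline:
                meds.append(candidate)
                have.add(candidate.atc_code)
        if len(meds) < want:
            raise RuntimeError(f"could not pad patient {p.patient_id} to {want} meds")
        patients[i] = PatientRecord(
            patient_id=p.patient_id, age_years=p.age_years, sex=p.sex,
            conditions=p.conditions, labs=p.labs, medications=tuple(meds),
        )

    cohort = Cohort(patients=tuple(patients), source="reference-fixture",
                    seed=_BUILD_SEED)
    _check_margins(cohort, assigned)
    return cohort


def _check_margins(cohort: Cohort, assigned: list[list[Bundle]]) -> None:
    from .cohort import medication_count_category
    from .engine import screen_cohort, tally

    table = screen_cohort(cohort)
    by_crit = tally(table, by="criterion").to_dict()
    if by_crit != ref.CRITERION_COUNTS:
        diff = {k: (ref.CRITERION_COUNTS.get(k, 0), by_crit.get(k, 0))
                for k in set(ref.CRITERION_COUNTS) | set(by_crit)
                if ref.CRITERION_COUNTS.get(k, 0) != by_crit.get(k, 0)}
        raise RuntimeError(f"fixture criterion counts deviate: {diff}")
    flagged = table.flagged_patients()
    bands = {(b, f): 0 for b in ("low", "mid", "high") for f in (True, False)}
    for p in cohort:
        bands[(medication_count_category(p), p.patient_id in flagged)] += 1
    expected = {}
    for j, b in enumerate(["low", "mid", "high"]):
        expected[(b, True)] = ref.KX2_TABLES["med_band"][j][0]
        expected[(b, False)] = ref.KX2_TABLES["med_band"][j][1]
    if bands != expected:
        raise RuntimeError(f"fixture med-band cross-tab deviates: {bands}")
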