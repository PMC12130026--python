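"""STOPP v3 rule evaluation engine.

Each of the 133 criteria is a declarative predicate over a patient's
medication tags, condition codes, laboratory panel, doses, durations, routes
and PRN flags.  Evaluation is tri-state:

* ``triggered`` — the rule fired; every medication (set) satisfying the drug
  clause is reported as a separate PIM instance;
* ``not_triggered`` — the rule's inputs were available and the rule did not
  fire;
* ``not_evaluable`` — a laboratory measurement the rule needs is missing, so
  "no data" is not conflated with "appropriate".  Not-evaluable outcomes are
  excluded from all tallies.

Instance counting: one flag per (patient, criterion, triggering drug set).
Several distinct drugs independently satisfying one criterion yield several
instances; the per-drug tally attributes each instance to the first (subject)
drug of its set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .cohort import Cohort, MedicationOrder, PatientRecord
from .drugs import AtcCatalog, load_catalog
from .vocab import SYSTEM_GROUPS

TRIGGERED = "triggered"
NOT_TRIGGERED = "not_triggered"
NOT_EVALUABLE = "not_evaluable"


class NotEvaluable:
    """Sentinel returned by a predicate missing a required input."""

    __slots__ = ("missing",)

    def __init__(self, *missing: str):
        self.missing = tuple(missing)


#: A predicate returns either a list of triggering drug sets (tuples of
#: orders, subject first; empty list = not triggered) or ``NotEvaluable``.
RuleResult = "list[tuple[MedicationOrder, ...]] | NotEvaluable"


@dataclass(frozen=True)
class CriterionDefinition:
    criterion_id: str
    system_group: str
    summary: str
    predicate: Callable[["PatientView"], RuleResult]

    @property
    def section(self) -> str:
        return self.criterion_id[0]


@dataclass(frozen=True)
class PIMFlag:
    patient_id: str
    criterion_id: str
    atc_codes: tuple[str, ...]     # subject drug first
    system_group: str

    @property
    def subject_code(self) -> str:
        return self.atc_codes[0]


@dataclass(frozen=True)
class EvaluationOutcome:
    criterion_id: str
    status: str
    missing_inputs: tuple[str, ...] = ()


class PatientView:
    """A patient plus cached drug-class tags, the input to every predicate."""

    def __init__(self, patient: PatientRecord, catalog: Optional[AtcCatalog] = None):
        self.patient = patient
        self.catalog = catalog or load_catalog()
        self._tags: list[frozenset[str]] = [
            self.catalog.classify(m.atc_code) for m in patient.medications
        ]

    # -- medications -------------------------------------------------------
    def tags_of(self, order: MedicationOrder) -> frozenset[str]:
        return self._tags[self.patient.medications.index(order)]

    def meds(
        self,
        *tags: str,
        regular: bool = False,
        route_in: Optional[Sequence[str]] = None,
        route_not: Optional[Sequence[str]] = None,
        min_days: Optional[int] = None,
        exclude_codes: Sequence[str] = (),
    ) -> list[MedicationOrder]:
        """Orders carrying any of ``tags`` (all orders when no tag given)."""
        out = []
        for m, t in zip(self.patient.medications, self._tags):
            if tags and not (t & frozenset(tags)):
                continue
            if regular and m.prn:
                continue
            if route_in and m.route not in route_in:
                continue
            if route_not and m.route in route_not:
                continue
            if min_days is not None and m.duration_days < min_days:
                continue
            if m.atc_code in exclude_codes:
                continue
            out.append(m)
        return out

    def on(self, *tags: str, **kw) -> bool:
        return bool(self.meds(*tags, **kw))

    # -- conditions and labs ----------------------------------------------
    def has(self, *conditions: str) -> bool:
        return bool(self.patient.conditions & frozenset(conditions))

    def lab(self, name: str) -> Optional[float]:
        return self.patient.labs.get(name)

    @property
    def sex(self) -> str:
        return self.patient.sex

    @property
    def age(self) -> int:
        return self.patient.age_years


@dataclass
class FlagTable:
    """Screening result for a cohort: all flags plus per-patient outcomes."""

    flags: list[PIMFlag] = field(default_factory=list)
    outcomes: dict[str, list[EvaluationOutcome]] = field(default_factory=dict)
    n_patients: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": f.patient_id,
                    "criterion_id": f.criterion_id,
                    "atc_codes": ";".join(f.atc_codes),
                    "system_group": f.system_group,
                }
                for f in self.flags
            ],
            columns=["patient_id", "criterion_id", "atc_codes", "system_group"],
        )

    def flagged_patients(self) -> set[str]:
        return {f.patient_id for f in self.flags}

    def __len__(self) -> int:
        return len(self.flags)


def get_criteria() -> dict[str, CriterionDefinition]:
    from . import rules  # late import: rules registers on import

    return rules.CRITERIA


def evaluate_criterion(
    criterion: CriterionDefinition | str,
    patient: PatientRecord | PatientView,
) -> tuple[EvaluationOutcome, list[PIMFlag]]:
    """Evaluate one criterion against one patient (side-effect free)."""
    if isinstance(criterion, str):
        registry = get_criteria()
        if criterion not in registry:
            raise KeyError(f"unknown criterion id {criterion!r}")
        criterion = registry[criterion]
    pv = patient if isinstance(patient, PatientView) else PatientView(patient)
    result = criterion.predicate(pv)
    if isinstance(result, NotEvaluable):
        return (
            EvaluationOutcome(criterion.criterion_id, NOT_EVALUABLE, result.missing),
            [],
        )
    flags = []
    seen: set[tuple[str, ...]] = set()
    for drug_set in result:
        codes = tuple(m.atc_code for m in drug_set)
        if codes in seen:
            continue
        seen.add(codes)
        flags.append(
            PIMFlag(
                patient_id=pv.patient.patient_id,
                criterion_id=criterion.criterion_id,
                atc_codes=codes,
                system_group=criterion.system_group,
            )
        )
    status = TRIGGERED if flags else NOT_TRIGGERED
    return EvaluationOutcome(criterion.criterion_id, status), flags


def screen_patient(patient: PatientRecord) -> list[PIMFlag]:
    """All PIM flags for one patient across the full criteria set."""
    pv = PatientView(patient)
    flags: list[PIMFlag] = []
    for crit in get_criteria().values():
        _, f = evaluate_criterion(crit, pv)
        flags.extend(f)
    return flags


def screen_patient_full(patient: PatientRecord) -> tuple[list[EvaluationOutcome], list[PIMFlag]]:
    pv = PatientView(patient)
    outcomes, flags = [], []
    for crit in get_criteria().values():
        o, f = evaluate_criterion(crit, pv)
        outcomes.append(o)
        flags.extend(f)
    return outcomes, flags


def screen_cohort(cohort: Cohort) -> FlagTable:
    """Screen every patient independently; deterministic and order-invariant
    up to flag order."""
    table = FlagTable(n_patients=len(cohort))
    for patient in cohort:
        outcomes, flags = screen_patient_full(patient)
        table.outcomes[patient.patient_id] = outcomes
        table.flags.extend(flags)
    return table


def tally(table: FlagTable, by: str = "criterion") -> pd.Series:
    """Count flags by ``criterion``, ``system``, ``drug`` (subject drug of
    each instance) or ``patient`` (distribution of PIMs per patient,
    including zero-PIM patients)."""
    if by == "criterion":
        counts = pd.Series(
            [f.criterion_id for f in table.flags], dtype="object"
        ).value_counts().sort_index()
    elif by == "system":
        counts = pd.Series(
            [f.system_group for f in table.flags], dtype="object"
        ).value_counts().sort_index()
    elif by == "drug":
        counts = pd.Series(
            [f.subject_code for f in table.flags], dtype="object"
        ).value_counts()
    elif by == "patient":
        per_patient = pd.Series(
            [f.patient_id for f in table.flags], dtype="object"
        ).value_counts()
        n_flagged = per_patient.value_counts().sort_index()
        n_zero = table.n_patients - len(per_patient)
        counts = pd.concat([pd.Series({0: n_zero}), n_flagged]).sort_index()
    else:
        raise ValueError(f"unknown tally axis {by!r}")
    counts.name = "count"
    return counts
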