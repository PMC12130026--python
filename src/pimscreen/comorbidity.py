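"""Charlson Comorbidity Index (CCI) scoring and study severity banding.

Uses the original (un-age-adjusted) Charlson weights: 17 condition groups
weighted 1, 2, 3 or 6; the score is the sum over groups present.  Within the
three graded pairs (diabetes vs. diabetes with end-organ damage, mild vs.
moderate/severe liver disease, any tumour vs. metastatic solid tumour) only
the more severe member scores, as in the original index.

Severity bands follow the study grouping: none (0), mild (1-2),
moderate (3-4), severe (>= 5).

The weight table ships as a packaged data file (``data/cci_weights.tsv``) so
the mapping from the condition vocabulary to index items is auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable

from .vocab import CHRONIC_COMORBIDITIES, CONDITIONS

#: (lesser item, greater item) pairs where only the more severe one scores.
_GRADED_PAIRS = [
    ("diabetes", "diabetes_end_organ_damage"),
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("any_tumor", "metastatic_solid_tumor"),
]


@dataclass(frozen=True)
class CCIResult:
    score: int
    band: str                      # none | mild | moderate | severe
    contributing_conditions: tuple[str, ...]


@lru_cache(maxsize=1)
def load_weight_table() -> dict[str, tuple[int, frozenset[str]]]:
    """item -> (weight, condition codes mapping onto the item)."""
    table: dict[str, tuple[int, frozenset[str]]] = {}
    path = resources.files("pimscreen.data") / "cci_weights.tsv"
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            conds = frozenset(c for c in row["conditions"].split(";") if c)
            unknown = conds - CONDITIONS
            if unknown:
                raise ValueError(f"cci_weights.tsv: unknown condition(s) {sorted(unknown)}")
            table[row["item"]] = (int(row["weight"]), conds)
    return table


def band_of(score: int) -> str:
    """Total severity banding of the raw score."""
    if score == 0:
        return "none"
    if score <= 2:
        return "mild"
    if score <= 4:
        return "moderate"
    return "severe"


def cci_score(conditions: Iterable[str]) -> CCIResult:
    """Score a condition set; conditions outside the index contribute 0."""
    conditions = frozenset(conditions)
    table = load_weight_table()
    present = {
        item for item, (_, codes) in table.items() if conditions & codes
    }
    for lesser, greater in _GRADED_PAIRS:
        if lesser in present and greater in present:
            present.discard(lesser)
    score = sum(table[item][0] for item in present)
    contributing = tuple(sorted(
        c for item in present for c in (table[item][1] & conditions)
    ))
    return CCIResult(score=score, band=band_of(score), contributing_conditions=contributing)


def comorbidity_category(conditions: Iterable[str]) -> str:
    """none (0 qualifying chronic conditions), comorbidity (1),
    multimorbidity (>= 2).

    The qualifying list (:data:`pimscreen.vocab.CHRONIC_COMORBIDITIES`)
    comprises the chronic diseases recorded at data collection plus the
    cardio-/cerebrovascular Charlson block; it is a module-level constant and
    so configurable by downstream code.
    """
    # graded variants of one disease count once (e.g. diabetes +- end-organ damage)
    groups = {
        "diabetes": {"diabetes_type2", "diabetes_complicated"},
        "cancer": {"cancer", "metastatic_cancer", "breast_cancer"},
        "cerebrovascular": {"stroke", "cerebrovascular_disease"},
        "ihd": {"coronary_artery_disease", "mi_history", "angina"},
        "heart_failure": {"heart_failure", "heart_failure_preserved_ef",
                          "heart_failure_nyha_3_4"},
    }
    present = frozenset(conditions) & CHRONIC_COMORBIDITIES
    n = 0
    seen: set[str] = set()
    for c in sorted(present):
        group = next((g for g, members in groups.items() if c in members), c)
        if group not in seen:
            seen.add(group)
            n += 1
    if n == 0:
        return "none"
    if n == 1:
        return "comorbidity"
    return "multimorbidity"
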