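"""Packaged ATC level-5 knowledge base.

Maps individual chemical substances (7-character WHO ATC codes) to the
pharmacological class tags referenced by the STOPP v3 predicates.  The catalog
is a curated, versioned subset of ATC shipped with the package: determinism
matters more here than completeness, because a screening run must classify the
same prescription identically forever.  One code may carry several tags
(e.g. carvedilol is a beta-blocker, non-selective, and a P-gp inhibitor).

Tag membership follows the class enumerations given in the rule text where
the rules enumerate members (e.g. the P-gp inhibitor and QTc-prolonging
lists); otherwise it follows the conventional ATC level-3/4 subtree for the
class.  Whether a drug counts as "systemic" is decided by the order's route,
not by the ATC code.
"""

from __future__ import annotations

import csv
import logging
from functools import lru_cache
from importlib import resources
from typing import Iterable

from .cohort import ATC_RE, MedicationOrder

log = logging.getLogger(__name__)

CATALOG_VERSION = "1.0"

#: Every pharmacological class tag used by at least one rule predicate.
DRUG_CLASS_TAGS: frozenset[str] = frozenset({
    "aspirin", "antiplatelet", "ticlopidine", "vitamin_k_antagonist",
    "direct_thrombin_inhibitor", "factor_xa_inhibitor", "anticoagulant",
    "heparin", "nsaid", "nsaid_nonselective", "cox2_selective",
    "ssri", "snri", "tca", "antidepressant",
    "benzodiazepine", "z_drug",
    "antipsychotic", "antipsychotic_anticholinergic", "phenothiazine",
    "first_gen_antihistamine", "second_gen_antihistamine",
    "opioid", "opioid_strong", "opioid_long_acting",
    "loop_diuretic", "thiazide", "aldosterone_antagonist",
    "ace_inhibitor", "arb", "beta_blocker", "beta_blocker_nonselective",
    "verapamil_diltiazem", "calcium_channel_blocker", "digoxin", "amiodarone",
    "central_antihypertensive", "alpha1_blocker", "alpha1_blocker_silodosin",
    "vasodilator", "nitrate", "pde5_inhibitor", "statin",
    "systemic_corticosteroid", "inhaled_corticosteroid", "inhaled_beta_agonist",
    "ppi", "h2_antagonist", "oral_iron", "metoclopramide_prochlorperazine",
    "sulfonylurea", "sulfonylurea_long_acting", "thiazolidinedione",
    "sglt2_inhibitor", "systemic_estrogen", "progestogen", "levothyroxine",
    "vasopressin_analog", "anticholinergic", "antiparkinson_anticholinergic",
    "urological_antimuscarinic", "acetylcholinesterase_inhibitor", "memantine",
    "nootropic", "levodopa_dopamine_agonist", "antiepileptic", "theophylline",
    "lama", "bisphosphonate", "colchicine", "xanthine_oxidase_inhibitor",
    "metformin", "nitrofurantoin", "methotrexate", "qtc_prolonging",
    "p_gp_inhibitor", "laxative", "antibiotic", "macrolide", "quinolone",
    "gabapentinoid", "paracetamol", "lithium", "megestrol", "mirabegron",
    "constipating", "lidocaine_patch",
})

#: Medication classes counted by the antihypertensive "monotherapy"/"first
#: line" clauses.
ANTIHYPERTENSIVE_TAGS: frozenset[str] = frozenset({
    "ace_inhibitor", "arb", "thiazide", "beta_blocker", "verapamil_diltiazem",
    "calcium_channel_blocker", "loop_diuretic", "central_antihypertensive",
    "alpha1_blocker", "aldosterone_antagonist",
})


class AtcCatalog:
    """Deterministic in-memory map from ATC level-5 code to name and tags."""

    def __init__(self, entries: dict[str, tuple[str, frozenset[str]]], version: str):
        self.entries = entries
        self.version = version

    def classify(self, atc_code: str) -> frozenset[str]:
        """Return the class tags for a syntactically valid ATC level-5 code.

        Unknown-but-valid codes return an empty tag set and log a warning;
        malformed codes raise ``ValueError``.
        """
        if not ATC_RE.match(atc_code):
            raise ValueError(f"malformed ATC level-5 code {atc_code!r}")
        entry = self.entries.get(atc_code)
        if entry is None:
            log.warning("ATC code %s not in catalog v%s; returning no tags",
                        atc_code, self.version)
            return frozenset()
        return entry[1]

    def name_of(self, atc_code: str) -> str:
        entry = self.entries.get(atc_code)
        return entry[0] if entry else ""

    def __contains__(self, atc_code: str) -> bool:
        return atc_code in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@lru_cache(maxsize=1)
def load_catalog() -> AtcCatalog:
    """Load the packaged catalog (cached; pure lookup afterwards)."""
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    path = resources.files("pimscreen.data") / "atc_catalog.tsv"
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["code", "name"]:
            raise ValueError("atc_catalog.tsv: unexpected header")
        for row in reader:
            if not row or not row[0].strip():
                continue
            code = row[0].strip()
            name = row[1].strip() if len(row) > 1 else ""
            raw = row[2].strip() if len(row) > 2 else ""
            tags = frozenset(t for t in raw.split(";") if t)
            if not ATC_RE.match(code):
                raise ValueError(f"atc_catalog.tsv: malformed code {code!r}")
            bad = tags - DRUG_CLASS_TAGS
            if bad:
                raise ValueError(f"atc_catalog.tsv: unknown tag(s) {sorted(bad)} for {code}")
            if code in entries:
                raise ValueError(f"atc_catalog.tsv: duplicate code {code}")
            entries[code] = (name, tags)
    return AtcCatalog(entries, CATALOG_VERSION)


def classify(atc_code: str) -> frozenset[str]:
    """Module-level convenience wrapper over the packaged catalog."""
    return load_catalog().classify(atc_code)


def anticholinergic_burden(meds: Iterable[MedicationOrder]) -> int:
    """Number of distinct regular (non-PRN) drugs with antimuscarinic
    properties on the medication list.

    Two or more such drugs constitute the anticholinergic-burden rule's
    trigger.  As-needed orders are excluded, mirroring the duplicate-class
    rule's "regular use as distinct from PRN" convention.
    """
    catalog = load_catalog()
    codes = {
        m.atc_code
        for m in meds
        if not m.prn and "anticholinergic" in catalog.classify(m.atc_code)
    }
    return len(codes)
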