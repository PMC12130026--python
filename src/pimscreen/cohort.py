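"""Patient, medication and cohort domain types with tabular readers/writers.

The canonical interchange format is JSON (one object per patient, nested
medication and condition arrays).  A two-table CSV layout (``patients.csv`` +
``medications.csv`` keyed by ``patient_id``) is supported for spreadsheet
workflows.  Validation is total: every malformed record raises a
:class:`CohortValidationError` naming the offending record and field; nothing
is silently coerced.  Laboratory units are fixed per field and never
converted.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .vocab import CONDITIONS

ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

ROUTES = ("oral", "parenteral", "topical", "transdermal", "inhaled", "other")
SEXES = ("male", "female")
DOSE_UNITS = ("mg", "ug", "g")
T4_STATUSES = ("low", "normal", "high")

MIN_AGE = 60  # inclusion threshold: hospitalized adults aged 60 and above


class CohortValidationError(ValueError):
    """A record violated the cohort schema or a domain invariant."""


@dataclass(frozen=True)
class MedicationOrder:
    """One prescribed drug, coded to ATC level 5.

    ``daily_dose`` is the total daily dose in ``dose_unit`` (mg, ug or g);
    ``duration_days`` is the length of continuous use to date; ``prn`` marks
    as-needed orders, which duplicate-class and anticholinergic-burden rules
    ignore.
    """

    atc_code: str
    name: str = ""
    daily_dose: float = 0.0
    dose_unit: str = "mg"
    route: str = "oral"
    prn: bool = False
    duration_days: int = 0
    indication_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not ATC_RE.match(self.atc_code):
            raise CohortValidationError(
                f"medication atc_code {self.atc_code!r} is not a valid ATC level-5 code"
            )
        if self.daily_dose < 0:
            raise CohortValidationError(
                f"medication {self.atc_code}: daily_dose must be >= 0, got {self.daily_dose}"
            )
        if self.dose_unit not in DOSE_UNITS:
            raise CohortValidationError(
                f"medication {self.atc_code}: unknown dose unit {self.dose_unit!r} "
                f"(units are fixed per field; no conversion is attempted)"
            )
        if self.route not in ROUTES:
            raise CohortValidationError(
                f"medication {self.atc_code}: unknown route {self.route!r}"
            )
        if self.duration_days < 0 or int(self.duration_days) != self.duration_days:
            raise CohortValidationError(
                f"medication {self.atc_code}: duration_days must be a non-negative "
                f"integer, got {self.duration_days}"
            )

    @property
    def dose_mg(self) -> float:
        """Daily dose normalised to milligrams (for dose-bounded rules)."""
        factor = {"mg": 1.0, "ug": 1e-3, "g": 1e3}[self.dose_unit]
        return self.daily_dose * factor

    def systemic(self) -> bool:
        return self.route in ("oral", "parenteral", "transdermal")


#: LabPanel numeric fields and their fixed units.
LAB_FIELDS = {
    "egfr": "mL/min/1.73m2",
    "serum_k": "mmol/L",
    "serum_na": "mmol/L",
    "corrected_ca": "mmol/L",
    "systolic_bp": "mmHg",
    "diastolic_bp": "mmHg",
    "heart_rate": "beats/min",
    "qtc_ms": "msec",
    "po2_kpa": "kPa",
    "pco2_kpa": "kPa",
    "tsh_mu_l": "mU/L",
    "bmi": "kg/m2",
}


@dataclass(frozen=True)
class LabPanel:
    """Optional laboratory measurements; ``None`` means not measured.

    A missing value is deliberately distinguishable from any numeric value:
    lab-dependent criteria become *not evaluable* rather than false when the
    measurement they need is absent.
    """

    egfr: Optional[float] = None
    serum_k: Optional[float] = None
    serum_na: Optional[float] = None
    corrected_ca: Optional[float] = None
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    heart_rate: Optional[float] = None
    qtc_ms: Optional[float] = None
    po2_kpa: Optional[float] = None
    pco2_kpa: Optional[float] = None
    tsh_mu_l: Optional[float] = None
    free_t4_status: Optional[str] = None
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        for name in LAB_FIELDS:
            value = getattr(self, name)
            if value is not None and not (isinstance(value, (int, float)) and value > 0):
                raise CohortValidationError(
                    f"lab {name}: present values must be strictly positive, got {value!r}"
                )
        if self.free_t4_status is not None and self.free_t4_status not in T4_STATUSES:
            raise CohortValidationError(
                f"lab free_t4_status must be one of {T4_STATUSES}, got {self.free_t4_status!r}"
            )

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


@dataclass(frozen=True)
class PatientRecord:
    """One hospitalized older adult (aged >= 60, on >= 1 medication)."""

    patient_id: str
    age_years: int
    sex: str
    conditions: frozenset[str] = frozenset()
    labs: LabPanel = field(default_factory=LabPanel)
    medications: tuple[MedicationOrder, ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be a non-empty string")
        pid = self.patient_id
        if self.age_years < MIN_AGE:
            raise CohortValidationError(
                f"patient {pid}: age below inclusion threshold {MIN_AGE} "
                f"(got {self.age_years})"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(f"patient {pid}: unknown sex {self.sex!r}")
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        unknown = self.conditions - CONDITIONS
        if unknown:
            raise CohortValidationError(
                f"patient {pid}: unknown condition code(s) {sorted(unknown)}"
            )
        object.__setattr__(self, "medications", tuple(self.medications))
        if not self.medications:
            raise CohortValidationError(
                f"patient {pid}: medications must be non-empty "
                f"(inclusion requires at least one prescription)"
            )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of validated patient records."""

    patients: tuple[PatientRecord, ...]
    source: str = "unspecified"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        if not self.patients:
            raise CohortValidationError("cohort must contain at least one patient")
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise CohortValidationError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def medication_count_category(patient: PatientRecord) -> str:
    """Medication-count band: ``low`` = 1-4, ``mid`` = 5-9, ``high`` = >=10.

    The three bands partition every possible count.  Polypharmacy (>= 4
    concurrent medications) spans the top of ``low`` plus ``mid`` and
    ``high``.
    """
    n = len(patient.medications)
    if n <= 4:
        return "low"
    if n <= 9:
        return "mid"
    return "high"


def is_polypharmacy(patient: PatientRecord) -> bool:
    """Polypharmacy: four or more concurrent medications."""
    return len(patient.medications) >= 4


# ---------------------------------------------------------------------------
# serialisation

def _patient_to_dict(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id,
        "age_years": p.age_years,
        "sex": p.sex,
        "conditions": sorted(p.conditions),
        "labs": {**p.labs.to_dict()},
        "medications": [
            {k: v for k, v in dataclasses.asdict(m).items() if v is not None}
            for m in p.medications
        ],
    }


def _patient_from_dict(d: dict, index: int) -> PatientRecord:
    try:
        labs = LabPanel(**d.get("labs", {}))
        meds = tuple(MedicationOrder(**m) for m in d.get("medications", []))
        return PatientRecord(
            patient_id=str(d["patient_id"]),
            age_years=int(d["age_years"]),
            sex=d["sex"],
            conditions=frozenset(d.get("conditions", [])),
            labs=labs,
            medications=meds,
        )
    except KeyError as exc:
        raise CohortValidationError(
            f"record {index}: missing required field {exc.args[0]!r}"
        ) from exc
    except TypeError as exc:
        raise CohortValidationError(f"record {index}: {exc}") from exc
    except CohortValidationError as exc:
        raise CohortValidationError(f"record {index}: {exc}") from exc


def write_cohort(cohort: Cohort, path: str | Path, format: str = "json") -> None:
    """Write a cohort to ``path``.

    JSON writes a single file.  CSV writes ``patients.csv`` and
    ``medications.csv`` inside the directory ``path`` (created if absent).
    Round-trip through :func:`read_cohort` is exact.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "format_version": "1",
            "source": cohort.source,
            "seed": cohort.seed,
            "patients": [_patient_to_dict(p) for p in cohort.patients],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=False))
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        prows, mrows = [], []
        for p in cohort.patients:
            row = {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "conditions": ";".join(sorted(p.conditions)),
            }
            for name in LAB_FIELDS:
                row[name] = p.labs.get(name)
            row["free_t4_status"] = p.labs.free_t4_status
            prows.append(row)
            for m in p.medications:
                mrows.append({"patient_id": p.patient_id, **dataclasses.asdict(m)})
        pd.DataFrame(prows).to_csv(path / "patients.csv", index=False)
        pd.DataFrame(mrows).to_csv(path / "medications.csv", index=False)
    else:
        raise ValueError(f"unknown cohort format {format!r}")


def read_cohort(path: str | Path, format: str = "json") -> Cohort:
    """Read and validate a cohort written by :func:`write_cohort`."""
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        patients = [
            _patient_from_dict(d, i) for i, d in enumerate(doc.get("patients", []))
        ]
        return Cohort(
            patients=tuple(patients),
            source=doc.get("source", "unspecified"),
            seed=doc.get("seed"),
        )
    if format == "csv":
        pdf = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
        mdf = pd.read_csv(path / "medications.csv", dtype={"patient_id": str})
        meds_by_pid: dict[str, list[MedicationOrder]] = {}
        for i, row in mdf.iterrows():
            d = row.to_dict()
            pid = d.pop("patient_id")
            ind = d.get("indication_code")
            if ind is None or (isinstance(ind, float) and math.isnan(ind)):
                d["indication_code"] = None
            d["name"] = "" if pd.isna(d.get("name")) else str(d["name"])
            try:
                order = MedicationOrder(
                    atc_code=str(d["atc_code"]),
                    name=d["name"],
                    daily_dose=float(d["daily_dose"]),
                    dose_unit=str(d["dose_unit"]),
                    route=str(d["route"]),
                    prn=bool(d["prn"]),
                    duration_days=int(d["duration_days"]),
                    indication_code=d["indication_code"],
                )
            except CohortValidationError as exc:
                raise CohortValidationError(f"medications.csv row {i}: {exc}") from exc
            meds_by_pid.setdefault(pid, []).append(order)
        patients = []
        for i, row in pdf.iterrows():
            labs_kwargs = {}
            for name in LAB_FIELDS:
                v = row.get(name)
                if v is not None and not pd.isna(v):
                    labs_kwargs[name] = float(v)
            t4 = row.get("free_t4_status")
            if t4 is not None and not pd.isna(t4):
                labs_kwargs["free_t4_status"] = str(t4)
            conds = row.get("conditions")
            conditions = (
                frozenset() if pd.isna(conds) or conds == "" else frozenset(str(conds).split(";"))
            )
            try:
                patients.append(
                    PatientRecord(
                        patient_id=str(row["patient_id"]),
                        age_years=int(row["age_years"]),
                        sex=str(row["sex"]),
                        conditions=conditions,
                        labs=LabPanel(**labs_kwargs),
                        medications=tuple(meds_by_pid.get(str(row["patient_id"]), [])),
                    )
                )
            except CohortValidationError as exc:
                raise CohortValidationError(f"patients.csv row {i}: {exc}") from exc
        return Cohort(patients=tuple(patients))
    raise ValueError(f"unknown cohort format {format!r}")
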