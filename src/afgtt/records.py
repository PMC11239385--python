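"""Core data model for an antifungal-exposed inpatient cohort.

One :class:`PatientRecord` is one hospital admission: demographics, a
laboratory time series, medication orders, free-text note events and
intervention flags.  Timestamps throughout are integer day-offsets from
admission (day 0 = admission day); chart review in trigger-tool studies works
at daily resolution.

On-disk layout (one directory per cohort, all UTF-8 text):

* ``patients.csv`` — one row per admission (demographics + stay-level fields)
* ``labs.csv``     — one row per laboratory result
* ``orders.csv``   — one row per medication order
* ``notes.jsonl``  — one JSON object per clinical-note event
* ``metadata.json`` — free-form provenance (seed, generator version)

Writing is deterministic: rows are sorted, columns fixed, so the same cohort
always serializes to identical bytes.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Sex",
    "Department",
    "Analyte",
    "DrugClass",
    "Route",
    "Demographics",
    "LabResult",
    "MedicationOrder",
    "NoteEvent",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

#: Minimum age at inclusion: 28 days, expressed in years.
MIN_AGE_YEARS = 28.0 / 365.0


class Sex(str, Enum):
    male = "male"
    female = "female"


class Department(str, Enum):
    internal = "internal"
    surgery = "surgery"


class Analyte(str, Enum):
    """Laboratory analytes referenced by the trigger set.

    Values are stored in one canonical unit per analyte: 10^9/L for the cell
    counts (PLT, WBC, NE), mmol/L for K, U/L for the enzymes (ALT, AST, ALP),
    multiples of the upper limit of normal for TBIL, mg/dL-free ratio-less
    mL/min for CRCL, and ug/mL for the voriconazole trough (VORI_CONC).
    BUN and SCR carry whatever absolute unit the source used; only their
    within-admission ratio to baseline is ever interpreted.
    """

    PLT = "PLT"
    WBC = "WBC"
    NE = "NE"
    BUN = "BUN"
    SCR = "SCR"
    CRCL = "CRCL"
    ALT = "ALT"
    AST = "AST"
    ALP = "ALP"
    TBIL = "TBIL"
    K = "K"
    VORI_CONC = "VORI_CONC"


class DrugClass(str, Enum):
    antifungal = "antifungal"
    antibacterial = "antibacterial"
    antihistamine = "antihistamine"
    antidiarrheal_probiotic = "antidiarrheal_probiotic"
    other = "other"


class Route(str, Enum):
    oral = "oral"
    iv = "iv"


class Demographics(BaseModel):
    patient_id: str
    age_years: float = Field(ge=MIN_AGE_YEARS)
    sex: Sex
    bmi: Optional[float] = None
    department: Department
    prior_hospitalizations: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_bmi(self) -> "Demographics":
        if self.bmi is not None and not (5.0 < self.bmi < 80.0):
            raise ValueError(
                f"patient {self.patient_id}: bmi {self.bmi} outside (5, 80)"
            )
        return self


class LabResult(BaseModel):
    analyte: Analyte
    value: float = Field(ge=0)
    day: int = Field(ge=0)


class MedicationOrder(BaseModel):
    drug_code: str
    drug_class: DrugClass
    start_day: int = Field(ge=0)
    stop_day: int = Field(ge=0)
    route: Route
    abrupt_stop: bool = False

    @model_validator(mode="after")
    def _check_span(self) -> "MedicationOrder":
        if self.stop_day < self.start_day:
            raise ValueError(
                f"order {self.drug_code}: stop_day {self.stop_day} < "
                f"start_day {self.start_day}"
            )
        # inclusion criterion: systemic antifungal administration for >= 24 h
        if self.drug_class is DrugClass.antifungal and self.stop_day < self.start_day + 1:
            raise ValueError(
                f"order {self.drug_code}: antifungal duration < 1 day"
            )
        return self


class NoteEvent(BaseModel):
    day: int = Field(ge=0)
    text: str


class PatientRecord(BaseModel):
    demographics: Demographics
    length_of_stay_days: int = Field(ge=1)
    labs: list[LabResult] = Field(default_factory=list)
    orders: list[MedicationOrder] = Field(default_factory=list)
    notes: list[NoteEvent] = Field(default_factory=list)
    icu_or_rescue: bool = False
    comorbidity_count: int = Field(ge=0)
    allergy_history: bool = False

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    @model_validator(mode="after")
    def _check_record(self) -> "PatientRecord":
        pid = self.demographics.patient_id
        for lab in self.labs:
            if lab.day > self.length_of_stay_days:
                raise ValueError(
                    f"patient {pid}: lab {lab.analyte.value} day {lab.day} "
                    f"beyond stay of {self.length_of_stay_days} days"
                )
        for note in self.notes:
            if note.day > self.length_of_stay_days:
                raise ValueError(
                    f"patient {pid}: note day {note.day} beyond stay"
                )
        if not any(o.drug_class is DrugClass.antifungal for o in self.orders):
            raise ValueError(f"patient {pid}: no antifungal order (inclusion)")
        return self

    def antifungal_start_day(self) -> int:
        """First day of systemic antifungal exposure."""
        return min(
            o.start_day for o in self.orders if o.drug_class is DrugClass.antifungal
        )


class Cohort(BaseModel):
    records: list[PatientRecord] = Field(default_factory=list)
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_unique_ids(self) -> "Cohort":
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def total_patient_days(self) -> int:
        return sum(r.length_of_stay_days for r in self.records)


class CohortValidationError(ValueError):
    """Raised when on-disk data violates a record invariant.

    The message names the offending patient_id and field.
    """


_PATIENT_COLS = [
    "patient_id",
    "age_years",
    "sex",
    "bmi",
    "department",
    "prior_hospitalizations",
    "length_of_stay_days",
    "icu_or_rescue",
    "comorbidity_count",
    "allergy_history",
]
_LAB_COLS = ["patient_id", "analyte", "value", "day"]
_ORDER_COLS = [
    "patient_id",
    "drug_code",
    "drug_class",
    "start_day",
    "stop_day",
    "route",
    "abrupt_stop",
]


def _fmt_num(x: float) -> str:
    """Render a number without float noise; integers lose the decimal point."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize ``cohort`` under directory ``path`` (created if needed).

    Output is byte-stable: records sorted by patient_id, labs/orders/notes in
    record order, fixed column order, LF line endings, sorted JSON keys.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    recs = sorted(cohort.records, key=lambda r: r.patient_id)

    prows, lrows, orows, nrows = [], [], [], []
    for r in recs:
        d = r.demographics
        prows.append(
            {
                "patient_id": d.patient_id,
                "age_years": _fmt_num(d.age_years),
                "sex": d.sex.value,
                "bmi": "" if d.bmi is None else _fmt_num(d.bmi),
                "department": d.department.value,
                "prior_hospitalizations": d.prior_hospitalizations,
                "length_of_stay_days": r.length_of_stay_days,
                "icu_or_rescue": int(r.icu_or_rescue),
                "comorbidity_count": r.comorbidity_count,
                "allergy_history": int(r.allergy_history),
            }
        )
        for lab in r.labs:
            lrows.append(
                {
                    "patient_id": d.patient_id,
                    "analyte": lab.analyte.value,
                    "value": _fmt_num(lab.value),
                    "day": lab.day,
                }
            )
        for o in r.orders:
            orows.append(
                {
                    "patient_id": d.patient_id,
                    "drug_code": o.drug_code,
                    "drug_class": o.drug_class.value,
                    "start_day": o.start_day,
                    "stop_day": o.stop_day,
                    "route": o.route.value,
                    "abrupt_stop": int(o.abrupt_stop),
                }
            )
        for note in r.notes:
            nrows.append(
                {"patient_id": d.patient_id, "day": note.day, "text": note.text}
            )

    pd.DataFrame(prows, columns=_PATIENT_COLS).to_csv(
        path / "patients.csv", index=False, lineterminator="\n"
    )
    pd.DataFrame(lrows, columns=_LAB_COLS).to_csv(
        path / "labs.csv", index=False, lineterminator="\n"
    )
    pd.DataFrame(orows, columns=_ORDER_COLS).to_csv(
        path / "orders.csv", index=False, lineterminator="\n"
    )
    with open(path / "notes.jsonl", "w", encoding="utf-8") as fh:
        for row in nrows:
            fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")
    with open(path / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.metadata, fh, ensure_ascii=False, sort_keys=True, indent=2)
        fh.write("\n")


def read_cohort(path: str | Path) -> Cohort:
    """Load and validate a cohort directory written by :func:`write_cohort`.

    Raises
    ------
    FileNotFoundError
        If the directory or a required file is missing.
    CohortValidationError
        If any record violates an invariant; the message names the
        patient_id and offending field.
    """
    path = Path(path)
    for fname in ("patients.csv", "labs.csv", "orders.csv", "notes.jsonl"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing cohort file: {path / fname}")

    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    labs = pd.read_csv(path / "labs.csv", dtype={"patient_id": str})
    orders = pd.read_csv(path / "orders.csv", dtype={"patient_id": str})
    notes: list[dict] = []
    with open(path / "notes.jsonl", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                notes.append(json.loads(line))
    metadata: dict = {}
    if (path / "metadata.json").exists():
        with open(path / "metadata.json", encoding="utf-8") as fh:
            metadata = json.load(fh)

    labs_by = {pid: g for pid, g in labs.groupby("patient_id")} if len(labs) else {}
    orders_by = {pid: g for pid, g in orders.groupby("patient_id")} if len(orders) else {}
    notes_by: dict[str, list[dict]] = {}
    for n in notes:
        notes_by.setdefault(str(n["patient_id"]), []).append(n)

    records = []
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        try:
            demo = Demographics(
                patient_id=pid,
                age_years=float(row["age_years"]),
                sex=row["sex"],
                bmi=None if pd.isna(row["bmi"]) else float(row["bmi"]),
                department=row["department"],
                prior_hospitalizations=int(row["prior_hospitalizations"]),
            )
            rec_labs = [
                LabResult(
                    analyte=lr["analyte"], value=float(lr["value"]), day=int(lr["day"])
                )
                for lr in labs_by.get(pid, pd.DataFrame()).to_dict("records")
            ]
            rec_orders = [
                MedicationOrder(
                    drug_code=orow["drug_code"],
                    drug_class=orow["drug_class"],
                    start_day=int(orow["start_day"]),
                    stop_day=int(orow["stop_day"]),
                    route=orow["route"],
                    abrupt_stop=bool(int(orow["abrupt_stop"])),
                )
                for orow in orders_by.get(pid, pd.DataFrame()).to_dict("records")
            ]
            rec_notes = [
                NoteEvent(day=int(n["day"]), text=str(n["text"]))
                for n in notes_by.get(pid, [])
            ]
            records.append(
                PatientRecord(
                    demographics=demo,
                    length_of_stay_days=int(row["length_of_stay_days"]),
                    labs=rec_labs,
                    orders=rec_orders,
                    notes=rec_notes,
                    icu_or_rescue=bool(int(row["icu_or_rescue"])),
                    comorbidity_count=int(row["comorbidity_count"]),
                    allergy_history=bool(int(row["allergy_history"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise CohortValidationError(f"patient {pid}: {exc}") from exc

    try:
        return Cohort(records=records, metadata=metadata)
    except ValueError as exc:
        raise CohortValidationError(str(exc)) from exc
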