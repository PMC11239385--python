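"""Declarative trigger set and screening engine.

A *trigger* is a screening rule whose firing on a chart flags the admission
for causality review.  The default set comprises 21 rules in four blocks:
7 laboratory indicators (L1-L7), 10 clinical-symptom keyword lists (S1-S10),
2 antidote-class medication rules (A1-A2) and 2 intervention flags (T1-T2).

Semantics:

* Lab thresholds use strict comparators exactly as written (e.g. K+ < 2.9
  mmol/L fires at 2.89, not at 2.9).
* L4 fires when BUN or serum creatinine rises above 2x its within-admission
  baseline (first recorded value), or when any creatinine clearance is below
  50 mL/min.
* Keyword rules are case-insensitive substring matches after whitespace
  normalization; negation is deliberately not handled (the tool is tuned for
  sensitivity; reviewers resolve false positives downstream).
* Symptom / antidote / intervention rules only count events on or after the
  first antifungal start day (exposure window); lab rules are evaluated over
  the whole stay so that baselines may precede exposure.
* Each trigger yields at most one hit per admission, at the earliest
  qualifying day; repeated crossings are one clinical episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Optional

import yaml

from .records import Analyte, Cohort, DrugClass, PatientRecord

__all__ = [
    "TriggerKind",
    "TriggerDefinition",
    "TriggerHit",
    "ScreenResult",
    "TriggerConfigError",
    "default_trigger_set",
    "save_trigger_set",
    "load_trigger_set",
    "eval_lab_trigger",
    "eval_baseline_ratio",
    "eval_keyword",
    "eval_medication",
    "eval_event_flag",
    "evaluate_trigger",
    "screen_record",
    "screen_cohort",
]


class TriggerKind(str, Enum):
    lab_threshold = "lab_threshold"
    lab_compound = "lab_compound"
    lab_baseline_ratio = "lab_baseline_ratio"
    drug_level = "drug_level"
    keyword = "keyword"
    medication_class = "medication_class"
    event_flag = "event_flag"


class TriggerConfigError(ValueError):
    """Malformed trigger definition (unknown analyte, empty keyword list...)."""


@dataclass(frozen=True)
class TriggerDefinition:
    """One declarative screening rule.

    ``params`` is kind-specific:

    * lab_threshold / drug_level: ``{"analyte", "comparator" ("<" or ">"),
      "threshold"}``
    * lab_compound: ``{"any": [clauses], "all_of": [clauses]}`` — fires when
      any single clause of ``any`` holds, or when every clause of ``all_of``
      has held at some point in the admission
    * lab_baseline_ratio: ``{"ratio_analytes", "ratio", "floor_analyte",
      "floor_threshold"}``
    * keyword: ``{"keywords": [str, ...]}``
    * medication_class: ``{"drug_class": str}``
    * event_flag: ``{"flag": "abrupt_stop" | "icu_or_rescue"}``
    """

    trigger_id: str
    kind: TriggerKind
    description: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TriggerHit:
    trigger_id: str
    patient_id: str
    day: int
    evidence: str


@dataclass
class ScreenResult:
    """Aggregate screening output over a cohort."""

    hits: list[TriggerHit]
    per_trigger_counts: dict[str, int]
    positive_patients: set[str]
    n_patients: int

    @property
    def n_hits(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# Default 21-trigger set
# ---------------------------------------------------------------------------

_S_KEYWORDS = {
    "S1": [
        "liver damage", "hepatotoxicity", "drug-induced hepatitis",
        "liver injury", "liver failure", "liver function abnormalities",
        "bilirubinemia", "jaundice", "cholestasis",
        "yellowing of the skin and sclera", "strong tea-like urine",
        "potter's clay-like stools", "stuffy epigastric area",
    ],
    "S2": [
        "myalgia", "bone pain", "back pain", "muscle pain", "joint pain",
        "periostitis",
    ],
    "S3": [
        "vision", "optical impairment", "photophobia", "green eyesight",
        "visual field defect", "yellow eyesight", "blue eyesight",
        "partially sighted", "blurred vision",
    ],
    "S4": [
        "rash", "itching", "erythema", "hyperpigmentation", "phototoxicity",
        "photosensitivity reaction", "drug rash", "skin lesions",
    ],
    "S5": [
        "mental disorders", "hallucination", "delirium",
        "visual hallucinations", "auditory hallucinations", "hyperactivity",
        "agitation", "verbosity", "depression", "irritability",
        "sensory abnormalities", "somnolence", "babbling", "photophobia",
        "psychotic symptoms",
    ],
    "S6": ["gastrointestinal discomfort", "nausea", "vomiting"],
    "S7": [
        "acute renal injury", "sunken edema", "general edema", "oliguria",
        "anuria",
    ],
    "S8": [
        "bleeding", "nosebleed", "gingival bleeding",
        "gastrointestinal bleeding", "vaginal bleeding",
    ],
    "S9": ["hypokalemia", "myasthenia"],
    "S10": ["phlebitis", "infusion reaction", "vascular redness and swelling"],
}

_S_DESCRIPTIONS = {
    "S1": "Liver damage / hepatotoxicity symptom cluster",
    "S2": "Myalgia / bone, back, muscle or joint pain",
    "S3": "Visual impairment symptom cluster",
    "S4": "Rash / skin reaction symptom cluster",
    "S5": "Mental-disorder symptom cluster",
    "S6": "Gastrointestinal discomfort such as nausea and vomiting",
    "S7": "Acute renal injury / edema / oliguria cluster",
    "S8": "Bleeding (nosebleed, gingival, gastrointestinal, vaginal)",
    "S9": "Hypokalemia and myasthenia",
    "S10": "Phlebitis / infusion reaction",
}


def default_trigger_set() -> list[TriggerDefinition]:
    """The 21-trigger antifungal set: 7 L + 10 S + 2 A + 2 T rules."""
    defs: list[TriggerDefinition] = [
        TriggerDefinition(
            "L1", TriggerKind.lab_threshold, "PLT < 50 x 10^9/L",
            {"analyte": "PLT", "comparator": "<", "threshold": 50.0},
        ),
        TriggerDefinition(
            "L2", TriggerKind.lab_threshold, "WBC < 3.0 x 10^9/L",
            {"analyte": "WBC", "comparator": "<", "threshold": 3.0},
        ),
        TriggerDefinition(
            "L3", TriggerKind.lab_threshold, "NE < 1.5 x 10^9/L",
            {"analyte": "NE", "comparator": "<", "threshold": 1.5},
        ),
        TriggerDefinition(
            "L4", TriggerKind.lab_baseline_ratio,
            "BUN or serum creatinine rising > 2x baseline, "
            "or creatinine clearance < 50 mL/min",
            {
                "ratio_analytes": ["BUN", "SCR"],
                "ratio": 2.0,
                "floor_analyte": "CRCL",
                "floor_threshold": 50.0,
            },
        ),
        TriggerDefinition(
            "L5", TriggerKind.lab_compound,
            "ALT > 84 U/L or AST > 80 U/L (or ALP > 121 U/L and TBIL > 2x ULN)",
            {
                "any": [
                    {"analyte": "ALT", "comparator": ">", "threshold": 84.0},
                    {"analyte": "AST", "comparator": ">", "threshold": 80.0},
                ],
                "all_of": [
                    {"analyte": "ALP", "comparator": ">", "threshold": 121.0},
                    {"analyte": "TBIL", "comparator": ">", "threshold": 2.0},
                ],
            },
        ),
        TriggerDefinition(
            "L6", TriggerKind.lab_threshold, "K+ < 2.9 mmol/L",
            {"analyte": "K", "comparator": "<", "threshold": 2.9},
        ),
        TriggerDefinition(
            "L7", TriggerKind.drug_level, "Voriconazole trough > 5 ug/mL",
            {"analyte": "VORI_CONC", "comparator": ">", "threshold": 5.0},
        ),
    ]
    for sid in (f"S{i}" for i in range(1, 11)):
        defs.append(
            TriggerDefinition(
                sid, TriggerKind.keyword, _S_DESCRIPTIONS[sid],
                {"keywords": list(_S_KEYWORDS[sid])},
            )
        )
    defs.append(
        TriggerDefinition(
            "A1", TriggerKind.medication_class,
            "Use of an antihistamine (diphenhydramine, loratadine, "
            "chlorphenamine, cetirizine, promethazine)",
            {"drug_class": "antihistamine"},
        )
    )
    defs.append(
        TriggerDefinition(
            "A2", TriggerKind.medication_class,
            "Use of a live intestinal bacteria preparation or antidiarrheal "
            "(e.g. montmorillonite)",
            {"drug_class": "antidiarrheal_probiotic"},
        )
    )
    defs.append(
        TriggerDefinition(
            "T1", TriggerKind.event_flag, "Abrupt cessation of medication",
            {"flag": "abrupt_stop"},
        )
    )
    defs.append(
        TriggerDefinition(
            "T2", TriggerKind.event_flag, "Admission to ICU / rescue",
            {"flag": "icu_or_rescue"},
        )
    )
    return defs


def save_trigger_set(triggers: list[TriggerDefinition], path: str | Path) -> None:
    payload = [
        {
            "trigger_id": t.trigger_id,
            "kind": t.kind.value,
            "description": t.description,
            "params": t.params,
        }
        for t in triggers
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def load_trigger_set(path: str | Path) -> list[TriggerDefinition]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    out = []
    seen = set()
    for item in payload:
        tid = item["trigger_id"]
        if tid in seen:
            raise TriggerConfigError(f"duplicate trigger_id {tid}")
        seen.add(tid)
        out.append(
            TriggerDefinition(
                trigger_id=tid,
                kind=TriggerKind(item["kind"]),
                description=item.get("description", ""),
                params=item.get("params", {}),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _check_analyte(name: str) -> Analyte:
    try:
        return Analyte(name)
    except ValueError as exc:
        raise TriggerConfigError(f"unknown analyte {name!r}") from exc


def _clause_holds(value: float, comparator: str, threshold: float) -> bool:
    if comparator == "<":
        return value < threshold
    if comparator == ">":
        return value > threshold
    raise TriggerConfigError(f"unknown comparator {comparator!r}")


def _earliest_clause_day(
    record: PatientRecord, clause: dict
) -> Optional[tuple[int, float]]:
    """Earliest (day, value) at which a single lab clause holds, else None."""
    analyte = _check_analyte(clause["analyte"])
    best: Optional[tuple[int, float]] = None
    for lab in record.labs:
        if lab.analyte is analyte and _clause_holds(
            lab.value, clause["comparator"], clause["threshold"]
        ):
            if best is None or lab.day < best[0]:
                best = (lab.day, lab.value)
    return best


def eval_lab_trigger(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    """Simple and compound lab-threshold rules (L1-L3, L5-L7)."""
    if definition.kind in (TriggerKind.lab_threshold, TriggerKind.drug_level):
        clause = {
            "analyte": definition.params["analyte"],
            "comparator": definition.params["comparator"],
            "threshold": definition.params["threshold"],
        }
        found = _earliest_clause_day(record, clause)
        if found is None:
            return []
        day, value = found
        ev = (
            f"{clause['analyte']}={value:g} {clause['comparator']} "
            f"{clause['threshold']:g} on day {day}"
        )
        return [TriggerHit(definition.trigger_id, record.patient_id, day, ev)]

    if definition.kind is TriggerKind.lab_compound:
        candidates: list[tuple[int, str]] = []
        for clause in definition.params.get("any", []):
            found = _earliest_clause_day(record, clause)
            if found is not None:
                day, value = found
                candidates.append((day, f"{clause['analyte']}={value:g} on day {day}"))
        all_of = definition.params.get("all_of", [])
        if all_of:
            # the conjunction is satisfied once every clause has held; it is
            # dated at the day the last clause first holds
            firsts = [_earliest_clause_day(record, c) for c in all_of]
            if all(f is not None for f in firsts):
                day = max(f[0] for f in firsts)  # type: ignore[index]
                desc = " and ".join(
                    f"{c['analyte']}={f[1]:g}" for c, f in zip(all_of, firsts)  # type: ignore[index]
                )
                candidates.append((day, f"{desc} by day {day}"))
        if not candidates:
            return []
        day, ev = min(candidates, key=lambda c: c[0])
        return [TriggerHit(definition.trigger_id, record.patient_id, day, ev)]

    raise TriggerConfigError(
        f"eval_lab_trigger got kind {definition.kind.value}"
    )


def eval_baseline_ratio(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    """Rise above a multiple of the within-admission baseline, or a floor (L4).

    The baseline is the first recorded value of the analyte in the admission;
    a single value can therefore never satisfy the ratio branch.
    """
    if definition.kind is not TriggerKind.lab_baseline_ratio:
        raise TriggerConfigError("eval_baseline_ratio expects lab_baseline_ratio")
    ratio = float(definition.params["ratio"])
    candidates: list[tuple[int, str]] = []
    for name in definition.params["ratio_analytes"]:
        analyte = _check_analyte(name)
        series = sorted(
            (lab for lab in record.labs if lab.analyte is analyte),
            key=lambda lab: lab.day,
        )
        if len(series) < 2:
            continue
        baseline = series[0].value
        if baseline <= 0:
            continue
        for lab in series[1:]:
            if lab.value > ratio * baseline:
                candidates.append(
                    (lab.day, f"{name}={lab.value:g} > {ratio:g}x baseline "
                              f"{baseline:g} on day {lab.day}")
                )
                break
    floor_name = definition.params.get("floor_analyte")
    if floor_name:
        found = _earliest_clause_day(
            record,
            {
                "analyte": floor_name,
                "comparator": "<",
                "threshold": definition.params["floor_threshold"],
            },
        )
        if found is not None:
            day, value = found
            candidates.append((day, f"{floor_name}={value:g} on day {day}"))
    if not candidates:
        return []
    day, ev = min(candidates, key=lambda c: c[0])
    return [TriggerHit(definition.trigger_id, record.patient_id, day, ev)]


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def eval_keyword(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    """Case-insensitive substring keyword match over note events (S1-S10)."""
    keywords = definition.params.get("keywords", [])
    if not keywords:
        raise TriggerConfigError(
            f"trigger {definition.trigger_id}: empty keyword list"
        )
    window_start = record.antifungal_start_day()
    normalized = [_normalize(k) for k in keywords]
    best: Optional[tuple[int, str]] = None
    for note in record.notes:
        if note.day < window_start:
            continue
        text = _normalize(note.text)
        for kw in normalized:
            if kw in text:
                if best is None or note.day < best[0]:
                    best = (note.day, f"matched {kw!r} on day {note.day}")
                break
    if best is None:
        return []
    return [TriggerHit(definition.trigger_id, record.patient_id, best[0], best[1])]


def eval_medication(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    """Antidote-class order starting on/after antifungal exposure (A1-A2)."""
    if definition.kind is not TriggerKind.medication_class:
        raise TriggerConfigError("eval_medication expects medication_class")
    target = DrugClass(definition.params["drug_class"])
    window_start = record.antifungal_start_day()
    best: Optional[tuple[int, str]] = None
    for order in record.orders:
        if order.drug_class is target and order.start_day >= window_start:
            if best is None or order.start_day < best[0]:
                best = (order.start_day,
                        f"{order.drug_code} started day {order.start_day}")
    if best is None:
        return []
    return [TriggerHit(definition.trigger_id, record.patient_id, best[0], best[1])]


def eval_event_flag(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    """Intervention flags: abrupt antifungal stop (T1), ICU/rescue (T2)."""
    if definition.kind is not TriggerKind.event_flag:
        raise TriggerConfigError("eval_event_flag expects event_flag")
    flag = definition.params["flag"]
    if flag == "abrupt_stop":
        stops = [
            o.stop_day
            for o in record.orders
            if o.drug_class is DrugClass.antifungal and o.abrupt_stop
        ]
        if not stops:
            return []
        day = min(stops)
        return [
            TriggerHit(
                definition.trigger_id, record.patient_id, day,
                f"abrupt antifungal stop on day {day}",
            )
        ]
    if flag == "icu_or_rescue":
        if not record.icu_or_rescue:
            return []
        day = record.length_of_stay_days
        return [
            TriggerHit(
                definition.trigger_id, record.patient_id, day,
                "ICU admission / rescue during stay",
            )
        ]
    raise TriggerConfigError(f"unknown event flag {flag!r}")


_DISPATCH: dict[TriggerKind, Callable[[PatientRecord, TriggerDefinition], list[TriggerHit]]] = {
    TriggerKind.lab_threshold: eval_lab_trigger,
    TriggerKind.lab_compound: eval_lab_trigger,
    TriggerKind.drug_level: eval_lab_trigger,
    TriggerKind.lab_baseline_ratio: eval_baseline_ratio,
    TriggerKind.keyword: eval_keyword,
    TriggerKind.medication_class: eval_medication,
    TriggerKind.event_flag: eval_event_flag,
}


def evaluate_trigger(
    record: PatientRecord, definition: TriggerDefinition
) -> list[TriggerHit]:
    return _DISPATCH[definition.kind](record, definition)


def screen_record(
    record: PatientRecord, triggers: list[TriggerDefinition]
) -> list[TriggerHit]:
    """Evaluate every trigger on one admission.

    At most one hit per trigger per admission; hits come back in trigger-set
    order, so screening is deterministic.
    """
    if not triggers:
        raise TriggerConfigError("empty trigger set")
    hits: list[TriggerHit] = []
    for definition in triggers:
        found = evaluate_trigger(record, definition)
        if found:
            hits.append(found[0])  # dedup: earliest hit only
    return hits


def screen_cohort(
    cohort: Cohort, triggers: list[TriggerDefinition]
) -> ScreenResult:
    """Screen every admission and aggregate per-trigger counts."""
    all_hits: list[TriggerHit] = []
    counts = {t.trigger_id: 0 for t in triggers}
    positive: set[str] = set()
    for record in cohort.records:
        hits = screen_record(record, triggers)
        all_hits.extend(hits)
        for h in hits:
            counts[h.trigger_id] += 1
        if hits:
            positive.add(record.patient_id)
    return ScreenResult(
        hits=all_hits,
        per_trigger_counts=counts,
        positive_patients=positive,
        n_patients=len(cohort.records),
    )
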