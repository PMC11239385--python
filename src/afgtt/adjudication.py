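"""Causality and severity adjudication of positive triggers.

Converts trigger hits plus structured review evidence into adjudicated
adverse-drug-event (ADE) records.  Causality follows the six-level WHO-UMC
scale (certain, probable, possible, unlikely, conditional, unassessable);
severity follows the CTCAE v5.0 general guideline (grades 1-5).  In the
manual workflow two junior reviewers assess each hit independently and two
senior reviewers arbitrate disagreements; here the evidence is structured,
so assessment is a deterministic decision tree and :func:`consensus` models
the arbitration step explicitly.

A hit counts as an ADE when its consensus causality is certain, probable or
possible; unlikely / conditional / unassessable hits are false-positive
triggers and yield no ADE record.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

from pydantic import BaseModel, model_validator

from .triggers import ScreenResult, TriggerHit

__all__ = [
    "TemporalRelationship",
    "OtherExplanation",
    "Dechallenge",
    "Rechallenge",
    "CausalityCategory",
    "CausalityEvidence",
    "Intervention",
    "SeverityEvidence",
    "SystemOrganClass",
    "ADERecord",
    "AdjudicationError",
    "assess_causality",
    "grade_severity",
    "consensus",
    "adjudicate_cohort",
    "DEFAULT_SOC_MAP",
]


class TemporalRelationship(str, Enum):
    plausible = "plausible"
    reasonable = "reasonable"
    improbable = "improbable"
    unknown = "unknown"


class OtherExplanation(str, Enum):
    excluded = "excluded"
    possible = "possible"
    likely = "likely"


class Dechallenge(str, Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"
    not_applicable = "not_applicable"


class Rechallenge(str, Enum):
    positive = "positive"
    negative = "negative"
    not_done = "not_done"


class CausalityCategory(str, Enum):
    certain = "certain"
    probable = "probable"
    possible = "possible"
    unlikely = "unlikely"
    conditional = "conditional"
    unassessable = "unassessable"

    @property
    def is_ade(self) -> bool:
        """Whether this category counts the event as a drug-related ADE."""
        return self in (
            CausalityCategory.certain,
            CausalityCategory.probable,
            CausalityCategory.possible,
        )


class CausalityEvidence(BaseModel):
    temporal_relationship: TemporalRelationship
    other_explanation: OtherExplanation
    dechallenge: Dechallenge
    rechallenge: Rechallenge
    pharmacologically_definitive: bool = False
    information_sufficient: bool = True
    more_data_pending: bool = False


def assess_causality(ev: CausalityEvidence) -> CausalityCategory:
    """Deterministic WHO-UMC decision tree.

    Categories are checked in a fixed order; the information-state categories
    (unassessable, conditional) come first because they describe whether a
    judgement can be made at all:

    1. unassessable — information insufficient or contradictory
    2. conditional — more data needed / under examination
    3. certain — plausible timing, other causes excluded, positive
       dechallenge or a pharmacologically definitive event, and rechallenge
       satisfactory if done (a negative rechallenge vetoes)
    4. probable — reasonable (or better) timing, other causes unlikely,
       positive dechallenge; rechallenge not required
    5. possible — reasonable (or better) timing; other causes and missing
       withdrawal information are allowed
    6. unlikely — timing improbable, or disease/other drugs provide the
       plausible explanation
    """
    if not ev.information_sufficient:
        return CausalityCategory.unassessable
    if ev.more_data_pending:
        return CausalityCategory.conditional
    timing_ok = ev.temporal_relationship in (
        TemporalRelationship.plausible,
        TemporalRelationship.reasonable,
    )
    if (
        ev.temporal_relationship is TemporalRelationship.plausible
        and ev.other_explanation is OtherExplanation.excluded
        and (ev.dechallenge is Dechallenge.positive or ev.pharmacologically_definitive)
        and ev.rechallenge is not Rechallenge.negative
    ):
        return CausalityCategory.certain
    if (
        timing_ok
        and ev.other_explanation is not OtherExplanation.likely
        and ev.dechallenge is Dechallenge.positive
    ):
        return CausalityCategory.probable
    if timing_ok:
        return CausalityCategory.possible
    return CausalityCategory.unlikely


class Intervention(str, Enum):
    none = "none"
    minimal_local_noninvasive = "minimal_local_noninvasive"
    hospitalization_or_prolongation = "hospitalization_or_prolongation"
    urgent = "urgent"


class SeverityEvidence(BaseModel):
    symptomatic: bool = False
    intervention: Intervention = Intervention.none
    limits_instrumental_adl: bool = False
    limits_selfcare_adl: bool = False
    life_threatening: bool = False
    death: bool = False


def grade_severity(ev: SeverityEvidence) -> int:
    """CTCAE v5.0 general guideline, highest applicable grade wins.

    5 death; 4 life-threatening / urgent intervention; 3 hospitalization (or
    prolongation) or limiting self-care ADL; 2 minimal/local/noninvasive
    intervention or limiting instrumental ADL; else 1.
    """
    if ev.death:
        return 5
    if ev.life_threatening or ev.intervention is Intervention.urgent:
        return 4
    if (
        ev.intervention is Intervention.hospitalization_or_prolongation
        or ev.limits_selfcare_adl
    ):
        return 3
    if (
        ev.intervention is Intervention.minimal_local_noninvasive
        or ev.limits_instrumental_adl
    ):
        return 2
    return 1


class AdjudicationError(ValueError):
    pass


def consensus(
    junior_a: CausalityCategory,
    junior_b: CausalityCategory,
    senior: Optional[CausalityCategory] = None,
) -> CausalityCategory:
    """Dual junior review with senior arbitration of disagreements."""
    if junior_a == junior_b:
        return junior_a
    if senior is None:
        raise AdjudicationError(
            f"junior reviewers disagree ({junior_a.value} vs {junior_b.value}) "
            "and no senior assessment was provided"
        )
    return senior


class SystemOrganClass(str, Enum):
    """Nine system-organ classes used to categorize antifungal ADEs."""

    metabolic_nutritional = "metabolic_nutritional"
    gastrointestinal = "gastrointestinal"
    skin_appendages = "skin_appendages"
    blood_lymphatic = "blood_lymphatic"
    urinary = "urinary"
    hepatobiliary = "hepatobiliary"
    vision = "vision"
    nervous_system = "nervous_system"
    musculoskeletal = "musculoskeletal"


#: Static trigger -> system-organ-class mapping used by the generators.
DEFAULT_SOC_MAP: dict[str, SystemOrganClass] = {
    "L1": SystemOrganClass.blood_lymphatic,
    "L2": SystemOrganClass.blood_lymphatic,
    "L3": SystemOrganClass.blood_lymphatic,
    "L4": SystemOrganClass.urinary,
    "L5": SystemOrganClass.hepatobiliary,
    "L6": SystemOrganClass.metabolic_nutritional,
    "L7": SystemOrganClass.metabolic_nutritional,
    "S1": SystemOrganClass.hepatobiliary,
    "S2": SystemOrganClass.musculoskeletal,
    "S3": SystemOrganClass.vision,
    "S4": SystemOrganClass.skin_appendages,
    "S5": SystemOrganClass.nervous_system,
    "S6": SystemOrganClass.gastrointestinal,
    "S7": SystemOrganClass.urinary,
    "S8": SystemOrganClass.blood_lymphatic,
    "S9": SystemOrganClass.metabolic_nutritional,
    "S10": SystemOrganClass.skin_appendages,
    "A1": SystemOrganClass.skin_appendages,
    "A2": SystemOrganClass.gastrointestinal,
    "T1": SystemOrganClass.gastrointestinal,
    "T2": SystemOrganClass.metabolic_nutritional,
}


@dataclass(frozen=True)
class ADERecord:
    """One adjudicated adverse drug event (causality possible or stronger)."""

    patient_id: str
    trigger_ids: tuple[str, ...]
    suspect_drug: str
    category: CausalityCategory
    grade: int
    soc: SystemOrganClass
    onset_day: int

    def __post_init__(self) -> None:
        if not self.category.is_ade:
            raise ValueError(
                f"ADERecord requires causality certain/probable/possible, "
                f"got {self.category.value}"
            )
        if not 1 <= self.grade <= 5:
            raise ValueError(f"grade {self.grade} outside [1, 5]")


#: Evidence attached to one hit: how the reviewers judged it.
HitEvidence = tuple[CausalityEvidence, SeverityEvidence, SystemOrganClass, str]


def _hit_key(hit: TriggerHit) -> tuple[str, str]:
    return (hit.patient_id, hit.trigger_id)


def adjudicate_cohort(
    screen: ScreenResult,
    evidence_map: Mapping[tuple[str, str], HitEvidence],
) -> list[ADERecord]:
    """Adjudicate every hit with available evidence.

    ``evidence_map`` is keyed by ``(patient_id, trigger_id)``.  Hits without
    evidence, or whose causality assesses to unlikely / conditional /
    unassessable, are false-positive triggers and produce no ADE record.
    Every evidence key must reference an actual hit.

    Returns one :class:`ADERecord` per confirmed hit (ADE instances, not
    patients; a patient may contribute several).
    """
    hit_keys = {_hit_key(h) for h in screen.hits}
    dangling = set(evidence_map) - hit_keys
    if dangling:
        raise AdjudicationError(
            f"evidence for non-existent hits: {sorted(dangling)[:5]}"
        )
    ades: list[ADERecord] = []
    for hit in screen.hits:
        entry = evidence_map.get(_hit_key(hit))
        if entry is None:
            continue
        causality_ev, severity_ev, soc, drug = entry
        # both junior reviewers apply the same deterministic tree and agree
        category = consensus(
            assess_causality(causality_ev), assess_causality(causality_ev)
        )
        if not category.is_ade:
            continue
        ades.append(
            ADERecord(
                patient_id=hit.patient_id,
                trigger_ids=(hit.trigger_id,),
                suspect_drug=drug,
                category=category,
                grade=grade_severity(severity_ev),
                soc=soc,
                onset_day=hit.day,
            )
        )
    return ades
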