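"""Synthetic cohort generation.

Two generators make the whole pipeline testable without any patient data:

* :func:`simulate_cohort` — parameterized random cohorts with known ground
  truth: ADE labels drawn at a configurable prevalence, each trigger planted
  with configurable conditional hit rates, and a review-evidence map emitted
  so that adjudication reproduces the labels exactly.
* :func:`simulate_logistic_cohort` — binned covariates drawn from
  chart-review-like marginals with a Bernoulli outcome from a known
  logistic model, for parameter-recovery and coverage checks.

The deterministic study-scale fixture lives in :mod:`afgtt.fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .adjudication import (
    DEFAULT_SOC_MAP,
    CausalityEvidence,
    Dechallenge,
    HitEvidence,
    Intervention,
    OtherExplanation,
    Rechallenge,
    SeverityEvidence,
    SystemOrganClass,
    TemporalRelationship,
)
from .records import (
    Cohort,
    Demographics,
    DrugClass,
    LabResult,
    MedicationOrder,
    NoteEvent,
    PatientRecord,
    Route,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_logistic_cohort",
    "TRIGGER_IDS",
    "plant_trigger",
    "evidence_for",
]

GENERATOR_VERSION = "1.0"

TRIGGER_IDS = [
    "L1", "L2", "L3", "L4", "L5", "L6", "L7",
    "S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10",
    "A1", "A2", "T1", "T2",
]

# Study-scale per-trigger counts: (positive instances, confirmed ADEs) over
# 480 admissions (142 ADE patients / 338 without).  These drive the default
# conditional hit rates below and the deterministic fixture.
STUDY_TRIGGER_COUNTS: dict[str, tuple[int, int]] = {
    "L1": (30, 4), "L2": (40, 11), "L3": (38, 10), "L4": (85, 18),
    "L5": (35, 13), "L6": (53, 21), "L7": (48, 18),
    "S1": (25, 6), "S2": (12, 2), "S3": (51, 8), "S4": (66, 14),
    "S5": (43, 7), "S6": (55, 23), "S7": (14, 5), "S8": (9, 1),
    "S9": (53, 17), "S10": (1, 1),
    "A1": (71, 18), "A2": (56, 15), "T1": (7, 2), "T2": (3, 0),
}

_N_ADE_PATIENTS = 142
_N_NO_ADE_PATIENTS = 338


def _default_rate_given_ade() -> dict[str, float]:
    return {
        t: ades / _N_ADE_PATIENTS for t, (_, ades) in STUDY_TRIGGER_COUNTS.items()
    }


def _default_rate_given_no_ade() -> dict[str, float]:
    return {
        t: (pos - ades) / _N_NO_ADE_PATIENTS
        for t, (pos, ades) in STUDY_TRIGGER_COUNTS.items()
    }


class SimulationConfig(BaseModel):
    """Generative parameters for a random antifungal-exposed cohort.

    Defaults are the study conditions: 480 admissions, ADE prevalence
    142/480, per-trigger conditional hit rates derived from the per-trigger
    instance counts, length of stay log-normal with mean 13.49 and SD 12.83
    days, and comorbidity count with mean about 5.4.
    """

    n_patients: int = Field(default=480, ge=1)
    seed: int = 0
    ade_prevalence: float = Field(default=_N_ADE_PATIENTS / 480.0, ge=0, le=1)
    per_trigger_hit_rate_given_ade: dict[str, float] = Field(
        default_factory=_default_rate_given_ade
    )
    per_trigger_hit_rate_given_no_ade: dict[str, float] = Field(
        default_factory=_default_rate_given_no_ade
    )
    los_mean_days: float = Field(default=13.49, gt=0)
    los_sd_days: float = Field(default=12.83, gt=0)
    comorbidity_mean: float = Field(default=5.41, gt=0)
    probability_probable: float = Field(default=21 / 214, ge=0, le=1)
    severity_probs: tuple[float, float, float] = (36 / 214, 160 / 214, 18 / 214)
    covariate_effects: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_rates(self) -> "SimulationConfig":
        for name, rates in (
            ("per_trigger_hit_rate_given_ade", self.per_trigger_hit_rate_given_ade),
            ("per_trigger_hit_rate_given_no_ade", self.per_trigger_hit_rate_given_no_ade),
        ):
            for t, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{name}[{t}] = {r} outside [0, 1]")
        if abs(sum(self.severity_probs) - 1.0) > 1e-9:
            raise ValueError("severity_probs must sum to 1")
        return self


@dataclass
class GroundTruth:
    """Labels and review evidence emitted alongside a generated cohort."""

    ade_patients: set[str]
    chart_review_only: set[str]  # ADE patients with no planted trigger
    evidence: dict[tuple[str, str], HitEvidence] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trigger planting
# ---------------------------------------------------------------------------

_LAB_PLANTS = {
    "L1": ("PLT", 40.0),
    "L2": ("WBC", 2.5),
    "L3": ("NE", 1.0),
    "L4": ("CRCL", 45.0),
    "L5": ("ALT", 100.0),
    "L6": ("K", 2.7),
    "L7": ("VORI_CONC", 6.0),
}

# one keyword per symptom trigger, chosen so the sentence matches exactly
# that trigger and no other
_NOTE_PLANTS = {
    "S1": "hepatotoxicity",
    "S2": "myalgia",
    "S3": "visual field defect",
    "S4": "drug rash",
    "S5": "delirium",
    "S6": "nausea",
    "S7": "oliguria",
    "S8": "gingival bleeding",
    "S9": "myasthenia",
    "S10": "phlebitis",
}

_ORDER_PLANTS = {
    "A1": ("loratadine", DrugClass.antihistamine),
    "A2": ("montmorillonite", DrugClass.antidiarrheal_probiotic),
}


@dataclass
class _RecordParts:
    """Mutable accumulator for one admission under construction."""

    labs: list[LabResult] = dc_field(default_factory=list)
    orders: list[MedicationOrder] = dc_field(default_factory=list)
    notes: list[NoteEvent] = dc_field(default_factory=list)
    icu_or_rescue: bool = False
    abrupt_stop_day: Optional[int] = None


def plant_trigger(parts: _RecordParts, trigger_id: str, day: int) -> None:
    """Insert the chart finding that makes ``trigger_id`` fire on ``day``."""
    if trigger_id in _LAB_PLANTS:
        analyte, value = _LAB_PLANTS[trigger_id]
        parts.labs.append(LabResult(analyte=analyte, value=value, day=day))
    elif trigger_id in _NOTE_PLANTS:
        kw = _NOTE_PLANTS[trigger_id]
        parts.notes.append(
            NoteEvent(day=day, text=f"Patient developed {kw} during antifungal therapy.")
        )
    elif trigger_id in _ORDER_PLANTS:
        code, cls = _ORDER_PLANTS[trigger_id]
        parts.orders.append(
            MedicationOrder(
                drug_code=code, drug_class=cls, start_day=day,
                stop_day=day + 1, route=Route.oral,
            )
        )
    elif trigger_id == "T1":
        parts.abrupt_stop_day = day
    elif trigger_id == "T2":
        parts.icu_or_rescue = True
    else:
        raise ValueError(f"unknown trigger {trigger_id!r}")


def evidence_for(
    trigger_id: str,
    category: str,
    grade: int,
    drug: str = "voriconazole",
) -> HitEvidence:
    """Structured review evidence that assesses to a wanted category/grade.

    ``category`` is one of "possible", "probable", "unlikely".
    """
    if category == "probable":
        cev = CausalityEvidence(
            temporal_relationship=TemporalRelationship.reasonable,
            other_explanation=OtherExplanation.excluded,
            dechallenge=Dechallenge.positive,
            rechallenge=Rechallenge.not_done,
        )
    elif category == "possible":
        cev = CausalityEvidence(
            temporal_relationship=TemporalRelationship.reasonable,
            other_explanation=OtherExplanation.possible,
            dechallenge=Dechallenge.unknown,
            rechallenge=Rechallenge.not_done,
        )
    elif category == "unlikely":
        cev = CausalityEvidence(
            temporal_relationship=TemporalRelationship.improbable,
            other_explanation=OtherExplanation.likely,
            dechallenge=Dechallenge.unknown,
            rechallenge=Rechallenge.not_done,
        )
    else:
        raise ValueError(f"unsupported target category {category!r}")
    if grade == 1:
        sev = SeverityEvidence(symptomatic=False, intervention=Intervention.none)
    elif grade == 2:
        sev = SeverityEvidence(
            symptomatic=True, intervention=Intervention.minimal_local_noninvasive
        )
    elif grade == 3:
        sev = SeverityEvidence(
            symptomatic=True,
            intervention=Intervention.hospitalization_or_prolongation,
        )
    else:
        raise ValueError(f"unsupported target grade {grade}")
    soc = DEFAULT_SOC_MAP.get(trigger_id, SystemOrganClass.metabolic_nutritional)
    return (cev, sev, soc, drug)


_ANTIFUNGALS = ["voriconazole", "fluconazole", "caspofungin"]
_ANTIBACTERIALS = [
    "ceftriaxone", "levofloxacin", "meropenem", "vancomycin",
    "piperacillin", "azithromycin", "cefepime",
]


def _assemble_record(
    patient_id: str,
    age: float,
    sex: str,
    bmi: Optional[float],
    department: str,
    prior_hosp: int,
    los: int,
    comorbidity: int,
    n_antifungal: int,
    n_antibacterial: int,
    parts: _RecordParts,
    allergy: bool = False,
) -> PatientRecord:
    orders = list(parts.orders)
    af_stop = max(2, min(5, los))
    for k in range(n_antifungal):
        orders.append(
            MedicationOrder(
                drug_code=_ANTIFUNGALS[k % len(_ANTIFUNGALS)],
                drug_class=DrugClass.antifungal,
                start_day=0,
                stop_day=parts.abrupt_stop_day if (k == 0 and parts.abrupt_stop_day) else af_stop,
                route=Route.iv,
                abrupt_stop=(k == 0 and parts.abrupt_stop_day is not None),
            )
        )
    for k in range(n_antibacterial):
        orders.append(
            MedicationOrder(
                drug_code=_ANTIBACTERIALS[k % len(_ANTIBACTERIALS)],
                drug_class=DrugClass.antibacterial,
                start_day=0,
                stop_day=min(3, los),
                route=Route.iv,
            )
        )
    return PatientRecord(
        demographics=Demographics(
            patient_id=patient_id,
            age_years=age,
            sex=sex,
            bmi=bmi,
            department=department,
            prior_hospitalizations=prior_hosp,
        ),
        length_of_stay_days=los,
        labs=list(parts.labs),
        orders=orders,
        notes=list(parts.notes),
        icu_or_rescue=parts.icu_or_rescue,
        comorbidity_count=comorbidity,
        allergy_history=allergy,
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


# marginal level probabilities used when drawing binned covariates
_MARGINALS = {
    "age": ([10.0, 30.0, 50.0, 70.0], [28, 69, 156, 227]),
    "bmi": ([17.0, 21.0, 26.0], [111, 285, 84]),
    "prior_hosp": ([1, 5, 8], [380, 50, 50]),
    "antifungal": ([1, 2, 3], [402, 66, 12]),
    "antibacterial": ([2, 5, 7], [403, 68, 9]),
}


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[Cohort, GroundTruth]:
    """Draw a random cohort with planted triggers and consistent evidence.

    Reproducible: the same config (and seed) always yields the same cohort.
    ``seed`` overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu, sigma = _lognormal_params(config.los_mean_days, config.los_sd_days)

    records: list[PatientRecord] = []
    truth = GroundTruth(ade_patients=set(), chart_review_only=set())
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        los = int(np.clip(round(rng.lognormal(mu, sigma)), 1, 112))
        age_vals, age_w = _MARGINALS["age"]
        age = float(rng.choice(age_vals, p=np.array(age_w) / sum(age_w)))
        sex = "male" if rng.random() < 320 / 480 else "female"
        dept = "internal" if rng.random() < 387 / 480 else "surgery"
        bmi_vals, bmi_w = _MARGINALS["bmi"]
        bmi = float(rng.choice(bmi_vals, p=np.array(bmi_w) / sum(bmi_w)))
        ph_vals, ph_w = _MARGINALS["prior_hosp"]
        prior = int(rng.choice(ph_vals, p=np.array(ph_w) / sum(ph_w)))
        af_vals, af_w = _MARGINALS["antifungal"]
        n_af = int(rng.choice(af_vals, p=np.array(af_w) / sum(af_w)))
        ab_vals, ab_w = _MARGINALS["antibacterial"]
        n_ab = int(rng.choice(ab_vals, p=np.array(ab_w) / sum(ab_w)))
        comorb = 1 + int(rng.poisson(max(config.comorbidity_mean - 1.0, 0.0)))

        is_ade = bool(rng.random() < config.ade_prevalence)
        if is_ade:
            truth.ade_patients.add(pid)

        parts = _RecordParts()
        fired: list[str] = []
        rates = (
            config.per_trigger_hit_rate_given_ade
            if is_ade
            else config.per_trigger_hit_rate_given_no_ade
        )
        for tid in TRIGGER_IDS:
            if rng.random() < rates.get(tid, 0.0):
                day = int(rng.integers(1, min(los, 6) + 1)) if los > 1 else 1
                day = min(day, los)
                plant_trigger(parts, tid, day)
                fired.append(tid)
        if is_ade and not fired:
            truth.chart_review_only.add(pid)
        for tid in fired:
            if is_ade:
                cat = (
                    "probable"
                    if rng.random() < config.probability_probable
                    else "possible"
                )
                grade = 1 + int(
                    rng.choice([0, 1, 2], p=np.asarray(config.severity_probs))
                )
            else:
                cat, grade = "unlikely", 1
            truth.evidence[(pid, tid)] = evidence_for(tid, cat, grade)

        records.append(
            _assemble_record(
                pid, age, sex, bmi, dept, prior, los, comorb, n_af, n_ab, parts
            )
        )
    cohort = Cohort(
        records=records,
        metadata={
            "generator": "simulate_cohort",
            "generator_version": GENERATOR_VERSION,
            "seed": int(config.seed if seed is None else seed),
            "n_patients": config.n_patients,
        },
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Logistic-model cohorts
# ---------------------------------------------------------------------------

_DESIGN_MARGINALS = {
    "los_bin": (["1-10", "11-20", "21-30", ">=31"], [263, 135, 36, 46]),
    "antifungal_bin": (["1", "2", "3"], [402, 66, 12]),
    "antibacterial_bin": (["0-3", "4-6", ">=7"], [403, 68, 9]),
    "trigger_bin": (["0-2", "3-5", ">=6"], [360, 97, 23]),
    "comorbidity_bin": (["1-3", "4-6", ">6"], [139, 195, 146]),
}


def simulate_logistic_cohort(
    beta: dict[str, float],
    n: int,
    seed: int,
    covariates: Optional[list[str]] = None,
):
    """Binned covariates from chart-review-like marginals, Bernoulli outcome.

    ``beta`` maps dummy-term names (e.g. ``"trigger_bin[3-5]"``) to log
    odds ratios, plus an optional ``"intercept"``.  Returns
    ``(design_frame, outcome_array)`` ready for
    :func:`afgtt.risk_factors.fit_logistic`.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    covariates = covariates or list(_DESIGN_MARGINALS)
    data = {}
    for cov in covariates:
        levels, weights = _DESIGN_MARGINALS[cov]
        p = np.asarray(weights, float)
        data[cov] = rng.choice(levels, size=n, p=p / p.sum())
    frame = pd.DataFrame(data)
    eta = np.full(n, beta.get("intercept", math.log(142 / 338)))
    for term, b in beta.items():
        if term == "intercept":
            continue
        cov, level = term.split("[", 1)
        level = level.rstrip("]")
        if cov not in frame.columns:
            raise ValueError(f"term {term!r} references unknown covariate")
        eta = eta + b * (frame[cov] == level).to_numpy(float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < prob).astype(int)
    return frame, outcome
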