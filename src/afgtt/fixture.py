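"""Deterministic study-scale fixture cohort.

:func:`make_study_fixture` builds, without any randomness, a 480-admission
cohort whose screening, adjudication and evaluation reproduce the published
study-scale counts simultaneously:

* per-trigger positive instances and confirmed ADEs for all 21 triggers
  (795 instances, 214 ADEs in total);
* 316 trigger-positive patients;
* the patient-level 2x2 table (138, 178, 4, 160) — including 4 ADE patients
  found only on chart review of trigger-negative admissions;
* causality split 193 possible / 21 probable and severity split
  36 / 160 / 18 (grades 1 / 2 / 3);
* covariate bin margins for both outcome groups;
* 6,476 total patient-days (mean stay 13.49 days).

Only the margins are pinned down by the published counts; the joint
assignment of hits to patients is a constructive choice.  Hits are assigned
by a largest-remaining-demand greedy (a Gale-Ryser style bipartite degree
realization), confirmed ADE hits first among ADE patients, then
false-positive hits among the remaining demand.  The finished cohort is
re-screened and re-adjudicated at build time and every targeted count is
verified; any mismatch raises :class:`FixtureError`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .adjudication import adjudicate_cohort
from .records import Cohort
from .synthetic import (
    GENERATOR_VERSION,
    STUDY_TRIGGER_COUNTS,
    TRIGGER_IDS,
    GroundTruth,
    _assemble_record,
    _RecordParts,
    evidence_for,
    plant_trigger,
)
from .triggers import default_trigger_set, screen_cohort

__all__ = ["FixtureError", "make_study_fixture"]


class FixtureError(RuntimeError):
    """Internal consistency check failed while building the fixture."""


N_PATIENTS = 480
N_ADE_PATIENTS = 142          # ADE patients (138 trigger-detected + 4 chart-only)
N_DETECTED = 138
N_CHART_ONLY = 4
TOTAL_PATIENT_DAYS = 6476

# --- per-group hit-count / confirmed-ADE-count composition ------------------
# (n_patients, hits_per_patient, confirmed_ades_per_patient)
_ADE_GROUPS = [
    (30, 1, 1),
    (28, 2, 2),
    (14, 3, 3),
    (20, 3, 2),
    (27, 3, 1),
    (19, 6, 1),
]
# (n_patients, hits_per_patient) for trigger-positive patients without ADEs
_NO_ADE_GROUPS = [
    (40, 1),
    (98, 2),
    (36, 4),
    (4, 8),
]

# --- covariate margins per outcome group (ADE n=142, no-ADE n=338) ----------
_LOS_VALUES = {"1-10": 6, "11-20": 14, "21-30": 25, ">=31": 45}
_LOS_COUNTS = {"ade": (48, 51, 20, 23), "no_ade": (215, 84, 16, 23)}
_AGE_VALUES = (10.0, 30.0, 50.0, 70.0)
_AGE_COUNTS = {"ade": (6, 18, 40, 78), "no_ade": (22, 51, 116, 149)}
_SEX_COUNTS = {"ade": (102, 40), "no_ade": (218, 120)}  # (male, female)
_DEPT_COUNTS = {"ade": (114, 28), "no_ade": (273, 65)}  # (internal, surgery)
_BMI_VALUES = (17.0, 21.0, 26.0)
_BMI_COUNTS = {"ade": (34, 90, 18), "no_ade": (77, 195, 66)}
_PRIOR_VALUES = (1, 5, 8)
_PRIOR_COUNTS = {"ade": (114, 15, 13), "no_ade": (266, 35, 37)}
_ANTIFUNGAL_VALUES = (1, 2, 3)
_ANTIFUNGAL_COUNTS = {"ade": (106, 27, 9), "no_ade": (296, 39, 3)}
_ANTIBACTERIAL_VALUES = (2, 5, 7)
_ANTIBACTERIAL_COUNTS = {"ade": (101, 36, 5), "no_ade": (302, 32, 4)}
_COMORBIDITY_VALUES = (2, 5, 7)
_COMORBIDITY_COUNTS = {"ade": (22, 72, 48), "no_ade": (117, 123, 98)}

_CAUSALITY_SPLIT = {"probable": 21, "possible": 193}
_SEVERITY_SPLIT = {1: 36, 2: 160, 3: 18}


def _expand(values, counts) -> list:
    out = []
    for v, c in zip(values, counts):
        out.extend([v] * c)
    return out


def _greedy_assign(
    column_sums: dict[str, int],
    demands: list[int],
    forbidden: list[set[str]],
) -> list[set[str]]:
    """Assign each trigger's instances to the rows with the largest remaining
    demand (bipartite degree-sequence realization), honouring per-row
    exclusions.  Returns the set of triggers per row."""
    remaining = list(demands)
    assigned: list[set[str]] = [set() for _ in demands]
    # largest columns first gives the greedy the most room
    for tid in sorted(column_sums, key=lambda t: (-column_sums[t], t)):
        need = column_sums[tid]
        if need == 0:
            continue
        eligible = [
            i
            for i in range(len(demands))
            if remaining[i] > 0 and tid not in forbidden[i] and tid not in assigned[i]
        ]
        eligible.sort(key=lambda i: (-remaining[i], i))
        if len(eligible) < need:
            raise FixtureError(
                f"cannot place {need} instances of {tid}; only "
                f"{len(eligible)} eligible patients remain"
            )
        for i in eligible[:need]:
            assigned[i].add(tid)
            remaining[i] -= 1
    if any(remaining):
        raise FixtureError(f"unfilled hit demand: {sum(remaining)} instances")
    return assigned


def _trigger_day(tid: str, k: int) -> int:
    # lab baselines are not needed (L4 is planted via the clearance branch);
    # stagger days a little for realism, always within the shortest stay
    return 1 + (k % 3)


def make_study_fixture() -> tuple[Cohort, GroundTruth]:
    """Build and verify the deterministic study-scale cohort.

    Returns ``(cohort, ground_truth)``; the ground truth carries the review
    evidence for every hit and the set of chart-review-only ADE patients.
    """
    # ---- per-patient hit plan ------------------------------------------
    ade_hit_demand: list[int] = []
    ade_confirm_demand: list[int] = []
    for n, hits, ades in _ADE_GROUPS:
        ade_hit_demand.extend([hits] * n)
        ade_confirm_demand.extend([ades] * n)
    no_ade_hit_demand: list[int] = []
    for n, hits in _NO_ADE_GROUPS:
        no_ade_hit_demand.extend([hits] * n)

    n_detected = len(ade_hit_demand)
    if n_detected != N_DETECTED:
        raise FixtureError("ADE group composition does not total 138 patients")

    ade_cols = {t: a for t, (_, a) in STUDY_TRIGGER_COUNTS.items()}
    fp_cols = {t: p - a for t, (p, a) in STUDY_TRIGGER_COUNTS.items()}

    # confirmed ADE hits among detected ADE patients
    confirmed = _greedy_assign(
        ade_cols, ade_confirm_demand, [set() for _ in ade_confirm_demand]
    )
    # false-positive hits: remaining demand of ADE patients, then the
    # trigger-positive no-ADE patients (a patient holds a trigger once)
    fp_demand = [
        h - c for h, c in zip(ade_hit_demand, ade_confirm_demand)
    ] + no_ade_hit_demand
    fp_forbidden = [set(s) for s in confirmed] + [
        set() for _ in no_ade_hit_demand
    ]
    false_pos = _greedy_assign(fp_cols, fp_demand, fp_forbidden)

    # ---- assemble patients ---------------------------------------------
    # order: 138 detected ADE, 4 chart-review-only ADE, 338 without ADE
    n_positive_no_ade = len(no_ade_hit_demand)
    n_negative_no_ade = N_PATIENTS - N_ADE_PATIENTS - n_positive_no_ade

    ade_ids = [f"F{i + 1:03d}" for i in range(N_ADE_PATIENTS)]
    no_ade_ids = [f"F{i + 1:03d}" for i in range(N_ADE_PATIENTS, N_PATIENTS)]

    per_patient_triggers: dict[str, tuple[set[str], set[str]]] = {}
    for i in range(N_DETECTED):
        per_patient_triggers[ade_ids[i]] = (confirmed[i], false_pos[i])
    for i in range(N_CHART_ONLY):
        per_patient_triggers[ade_ids[N_DETECTED + i]] = (set(), set())
    for j in range(n_positive_no_ade):
        per_patient_triggers[no_ade_ids[j]] = (set(), false_pos[N_DETECTED + j])
    for j in range(n_positive_no_ade, n_positive_no_ade + n_negative_no_ade):
        per_patient_triggers[no_ade_ids[j]] = (set(), set())

    # per-group covariate assignments, in patient order within each group
    groups = {
        "ade": ade_ids,
        "no_ade": no_ade_ids,
    }
    covariates: dict[str, dict] = {pid: {} for pid in per_patient_triggers}

    def _spread(values, counts, tag: str) -> list:
        # margins are pinned; the within-group order is not, so permute each
        # covariate independently (fixed per-covariate seed) to avoid the
        # aligned blocks that _expand alone would produce — aligned blocks
        # make the covariates perfectly collinear within each outcome group
        # and the joint design quasi-separable
        out = _expand(values, counts)
        seed = zlib.crc32(tag.encode("utf-8"))
        np.random.default_rng(seed).shuffle(out)
        return out

    for g, ids in groups.items():
        los = _spread(list(_LOS_VALUES.values()), _LOS_COUNTS[g], f"{g}:los")
        age = _spread(_AGE_VALUES, _AGE_COUNTS[g], f"{g}:age")
        sex = _spread(("male", "female"), _SEX_COUNTS[g], f"{g}:sex")
        dept = _spread(("internal", "surgery"), _DEPT_COUNTS[g], f"{g}:dept")
        bmi = _spread(_BMI_VALUES, _BMI_COUNTS[g], f"{g}:bmi")
        prior = _spread(_PRIOR_VALUES, _PRIOR_COUNTS[g], f"{g}:prior")
        n_af = _spread(_ANTIFUNGAL_VALUES, _ANTIFUNGAL_COUNTS[g], f"{g}:n_af")
        n_ab = _spread(_ANTIBACTERIAL_VALUES, _ANTIBACTERIAL_COUNTS[g], f"{g}:n_ab")
        comorb = _spread(
            _COMORBIDITY_VALUES, _COMORBIDITY_COUNTS[g], f"{g}:comorb"
        )
        for k, pid in enumerate(ids):
            covariates[pid] = {
                "los": los[k], "age": age[k], "sex": sex[k], "dept": dept[k],
                "bmi": bmi[k], "prior": prior[k], "n_af": n_af[k],
                "n_ab": n_ab[k], "comorb": comorb[k],
            }

    # pin total patient-days at 6,476: the long-stay bin averages just under
    # 46 days, so 38 of its 46 patients get 46 days and 8 get 45
    long_stay = [pid for pid in ade_ids + no_ade_ids if covariates[pid]["los"] == 45]
    if len(long_stay) != 46:
        raise FixtureError("long-stay bin does not hold 46 patients")
    for pid in long_stay[:38]:
        covariates[pid]["los"] = 46

    # ---- build records and evidence ------------------------------------
    all_ids = ade_ids + no_ade_ids
    truth = GroundTruth(
        ade_patients=set(ade_ids),
        chart_review_only=set(ade_ids[N_DETECTED:]),
    )

    # deterministic ordering of confirmed hits drives the causality and
    # severity overlays
    confirmed_hits: list[tuple[str, str]] = []
    for i, pid in enumerate(ade_ids[:N_DETECTED]):
        for tid in sorted(confirmed[i], key=TRIGGER_IDS.index):
            confirmed_hits.append((pid, tid))
    if len(confirmed_hits) != sum(ade_cols.values()):
        raise FixtureError("confirmed hit count mismatch")
    categories = ["probable"] * _CAUSALITY_SPLIT["probable"] + ["possible"] * (
        _CAUSALITY_SPLIT["possible"]
    )
    grades = (
        [1] * _SEVERITY_SPLIT[1] + [2] * _SEVERITY_SPLIT[2] + [3] * _SEVERITY_SPLIT[3]
    )
    for (pid, tid), cat, grade in zip(confirmed_hits, categories, grades):
        truth.evidence[(pid, tid)] = evidence_for(tid, cat, grade)

    records = []
    for pid in all_ids:
        cov = covariates[pid]
        conf, fp = per_patient_triggers[pid]
        parts = _RecordParts()
        for k, tid in enumerate(sorted(conf | fp, key=TRIGGER_IDS.index)):
            plant_trigger(parts, tid, _trigger_day(tid, k))
        for tid in sorted(fp, key=TRIGGER_IDS.index):
            truth.evidence[(pid, tid)] = evidence_for(tid, "unlikely", 1)
        records.append(
            _assemble_record(
                pid, cov["age"], cov["sex"], cov["bmi"], cov["dept"],
                cov["prior"], cov["los"], cov["comorb"], cov["n_af"],
                cov["n_ab"], parts,
            )
        )
    cohort = Cohort(
        records=records,
        metadata={
            "generator": "make_study_fixture",
            "generator_version": GENERATOR_VERSION,
            "deterministic": True,
        },
    )
    _verify(cohort, truth)
    return cohort, truth


def _verify(cohort: Cohort, truth: GroundTruth) -> None:
    """Re-screen and re-adjudicate the built cohort against every target."""
    screen = screen_cohort(cohort, default_trigger_set())
    expected_counts = {t: p for t, (p, _) in STUDY_TRIGGER_COUNTS.items()}
    if screen.per_trigger_counts != expected_counts:
        diff = {
            t: (screen.per_trigger_counts.get(t), expected_counts[t])
            for t in expected_counts
            if screen.per_trigger_counts.get(t) != expected_counts[t]
        }
        raise FixtureError(f"per-trigger counts off: {diff}")
    if len(screen.positive_patients) != 316:
        raise FixtureError(
            f"positive patients {len(screen.positive_patients)} != 316"
        )
    ades = adjudicate_cohort(screen, truth.evidence)
    if len(ades) != 214:
        raise FixtureError(f"ADE instances {len(ades)} != 214")
    by_trigger: dict[str, int] = {}
    for a in ades:
        for t in a.trigger_ids:
            by_trigger[t] = by_trigger.get(t, 0) + 1
    expected_ades = {t: a for t, (_, a) in STUDY_TRIGGER_COUNTS.items() if a}
    if by_trigger != expected_ades:
        raise FixtureError("per-trigger ADE counts off")
    detected = {a.patient_id for a in ades}
    if len(detected) != N_DETECTED:
        raise FixtureError(f"detected ADE patients {len(detected)} != 138")
    cats = {c: sum(1 for a in ades if a.category.value == c) for c in
            ("possible", "probable")}
    if cats != {"possible": 193, "probable": 21}:
        raise FixtureError(f"causality split off: {cats}")
    sev = {g: sum(1 for a in ades if a.grade == g) for g in (1, 2, 3)}
    if sev != _SEVERITY_SPLIT:
        raise FixtureError(f"severity split off: {sev}")
    if cohort.total_patient_days() != TOTAL_PATIENT_DAYS:
        raise FixtureError(
            f"patient-days {cohort.total_patient_days()} != {TOTAL_PATIENT_DAYS}"
        )
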