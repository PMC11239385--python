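"""Trigger-validity statistics and ADE rate calculations.

The trigger tool is evaluated at two levels:

* instance level — positive predictive value (PPV): confirmed ADE instances
  divided by positive trigger instances, overall and per trigger;
* patient level — a 2x2 table of trigger-positive vs ADE-positive patients,
  from which sensitivity, specificity, the Youden (accuracy) index and
  Cohen's kappa are derived.

Rates use admissions and patient-days as denominators: ADE incidence among
inpatients, ADEs per 100 admissions, and ADEs per 1,000 patient-days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from scipy import stats

from .adjudication import ADERecord
from .triggers import ScreenResult

__all__ = [
    "ContingencyTable",
    "TriggerPerformance",
    "CohortMetrics",
    "SampleSizeParams",
    "UndefinedMetricError",
    "per_trigger_performance",
    "overall_ppv",
    "build_2x2",
    "validity_metrics",
    "rate_metrics",
    "two_proportion_test",
    "sample_size",
    "compute_cohort_metrics",
    "round_half_up",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator (or table margin) is zero."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as the printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Patient-level 2x2: trigger detection x ADE determination."""

    tp: int  # trigger-positive, ADE
    fp: int  # trigger-positive, no ADE
    fn: int  # trigger-negative, ADE
    tn: int  # trigger-negative, no ADE

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class TriggerPerformance:
    trigger_id: str
    positive_count: int
    ade_count: int
    ppv: Optional[float]  # None when the trigger never fired

    def __post_init__(self) -> None:
        if self.ade_count > self.positive_count:
            raise ValueError(
                f"{self.trigger_id}: ade_count {self.ade_count} exceeds "
                f"positive_count {self.positive_count}"
            )


@dataclass(frozen=True)
class CohortMetrics:
    """All cohort-level validity and rate statistics (full precision)."""

    overall_ppv: float
    sensitivity: float
    specificity: float
    youden: float
    kappa: float
    incidence: float
    ades_per_100_admissions: float
    ades_per_1000_patient_days: float
    positive_trigger_rate: float
    mean_hits_per_patient: float
    false_negative_rate: float
    table: ContingencyTable
    n_hits: int
    n_ades: int

    def as_dict(self) -> dict:
        return {
            "overall_ppv": self.overall_ppv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "kappa": self.kappa,
            "incidence": self.incidence,
            "ades_per_100_admissions": self.ades_per_100_admissions,
            "ades_per_1000_patient_days": self.ades_per_1000_patient_days,
            "positive_trigger_rate": self.positive_trigger_rate,
            "mean_hits_per_patient": self.mean_hits_per_patient,
            "false_negative_rate": self.false_negative_rate,
            "n_hits": self.n_hits,
            "n_ades": self.n_ades,
            "table": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
            },
        }


@dataclass(frozen=True)
class SampleSizeParams:
    """Single-proportion sample-size inputs: N = Z^2 P (1-P) / delta^2."""

    P: float
    Z: float = 1.96
    delta: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.P < 1:
            raise ValueError("P must lie in (0, 1)")
        if self.Z <= 0 or not 0 < self.delta < 1:
            raise ValueError("Z must be positive and delta in (0, 1)")


def sample_size(params: SampleSizeParams) -> int:
    """Required N for estimating a proportion P within sampling error delta."""
    n = params.Z**2 * params.P * (1.0 - params.P) / params.delta**2
    return int(round_half_up(n, 0))


def per_trigger_performance(
    screen: ScreenResult, ades: Iterable[ADERecord]
) -> list[TriggerPerformance]:
    """Positive instances, confirmed ADEs and PPV for every trigger.

    PPV is None (not-applicable) for triggers that never fired; 0 positives
    is evidence of an unused trigger, not of a worthless one.
    """
    ade_counts: dict[str, int] = {}
    for ade in ades:
        for tid in ade.trigger_ids:
            ade_counts[tid] = ade_counts.get(tid, 0) + 1
    unknown = set(ade_counts) - set(screen.per_trigger_counts)
    if unknown:
        raise ValueError(f"ADEs reference unscreened triggers: {sorted(unknown)}")
    out = []
    for tid, pos in screen.per_trigger_counts.items():
        n_ade = ade_counts.get(tid, 0)
        out.append(
            TriggerPerformance(
                trigger_id=tid,
                positive_count=pos,
                ade_count=n_ade,
                ppv=(n_ade / pos) if pos > 0 else None,
            )
        )
    return out


def overall_ppv(total_ades: int, total_hits: int) -> float:
    """Instance-level PPV: confirmed ADE instances / positive trigger instances."""
    if total_hits <= 0:
        raise UndefinedMetricError("PPV undefined with zero trigger instances")
    return total_ades / total_hits


def build_2x2(
    positive_patients: set[str], ade_patients: set[str], all_patients: set[str]
) -> ContingencyTable:
    """Patient-level four-grid table of trigger detection vs ADE occurrence."""
    if not positive_patients <= all_patients or not ade_patients <= all_patients:
        raise ValueError("positive/ADE patient sets must be subsets of the cohort")
    tp = len(positive_patients & ade_patients)
    fp = len(positive_patients - ade_patients)
    fn = len(ade_patients - positive_patients)
    tn = len(all_patients) - tp - fp - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def validity_metrics(ct: ContingencyTable) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, Youden index, Cohen's kappa) of a 2x2.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement from the table margins.
    """
    n = ct.total
    if ct.tp + ct.fn == 0:
        raise UndefinedMetricError("no ADE-positive patients (tp + fn = 0)")
    if ct.fp + ct.tn == 0:
        raise UndefinedMetricError("no ADE-negative patients (fp + tn = 0)")
    sens = ct.tp / (ct.tp + ct.fn)
    spec = ct.tn / (ct.fp + ct.tn)
    youden = sens + spec - 1.0
    po = (ct.tp + ct.tn) / n
    pe = (
        (ct.tp + ct.fp) * (ct.tp + ct.fn) + (ct.fn + ct.tn) * (ct.fp + ct.tn)
    ) / n**2
    kappa = 0.0 if math.isclose(pe, 1.0) else (po - pe) / (1.0 - pe)
    return sens, spec, youden, kappa


def rate_metrics(
    n_ades: int,
    n_ade_patients_detected: int,
    n_patients: int,
    total_patient_days: int,
) -> tuple[float, float, float]:
    """(incidence, ADEs per 100 admissions, ADEs per 1,000 patient-days).

    Incidence counts trigger-detected ADE patients; the ADE-instance rates
    use all confirmed instances.
    """
    if n_patients <= 0 or total_patient_days <= 0:
        raise UndefinedMetricError("rate denominators must be positive")
    incidence = n_ade_patients_detected / n_patients
    per_100 = 100.0 * n_ades / n_patients
    per_1000_pd = 1000.0 * n_ades / total_patient_days
    return incidence, per_100, per_1000_pd


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on two proportions.

    Used to compare the trigger-detected ADE rate with the spontaneous
    reporting system's rate over the same period.
    """
    if n1 <= 0 or n2 <= 0:
        raise UndefinedMetricError("group sizes must be positive")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; an exact test would be preferable",
            stacklevel=2,
        )
    if x1 + x2 == 0 or (n1 - x1) + (n2 - x2) == 0:
        return 0.0, 1.0  # degenerate margin: proportions identical
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compute_cohort_metrics(
    screen: ScreenResult,
    ades: list[ADERecord],
    all_patients: set[str],
    total_patient_days: int,
    chart_review_ade_patients: set[str] | None = None,
) -> CohortMetrics:
    """Assemble every cohort-level statistic from a screening + adjudication.

    ``chart_review_ade_patients`` are ADE patients found only by full chart
    review of trigger-negative admissions (false negatives of the tool); they
    enter the 2x2 and the false-negative rate but not the incidence, which by
    convention counts trigger-detected ADE patients.
    """
    chart_review_ade_patients = chart_review_ade_patients or set()
    detected = {a.patient_id for a in ades}
    ade_patients = detected | chart_review_ade_patients
    n_patients = len(all_patients)
    if n_patients == 0:
        raise UndefinedMetricError("empty cohort")
    ct = build_2x2(screen.positive_patients, ade_patients, all_patients)
    sens, spec, youden, kappa = validity_metrics(ct)
    incidence, per_100, per_1000 = rate_metrics(
        len(ades), len(detected), n_patients, total_patient_days
    )
    fnr = ct.fn / (ct.tp + ct.fn)
    return CohortMetrics(
        overall_ppv=overall_ppv(len(ades), screen.n_hits),
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        kappa=kappa,
        incidence=incidence,
        ades_per_100_admissions=per_100,
        ades_per_1000_patient_days=per_1000,
        positive_trigger_rate=len(screen.positive_patients) / n_patients,
        mean_hits_per_patient=screen.n_hits / n_patients,
        false_negative_rate=fnr,
        table=ct,
        n_hits=screen.n_hits,
        n_ades=len(ades),
    )
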