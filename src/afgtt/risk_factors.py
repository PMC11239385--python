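"""Risk-factor analysis: covariate binning, univariate tests and binary
logistic regression with Wald odds-ratio confidence intervals.

Covariates are the chart-review characteristics: age, sex, department,
length of stay, BMI, prior hospitalizations, numbers of combined antifungal
and antibacterial agents, number of positive triggers and number of
comorbid diseases, each cut into the bins used on review forms.  The model
is a main-effects binary logistic regression of ADE occurrence on the
binned covariates with dummy coding against declared reference levels,
fitted by iteratively reweighted least squares (IRLS); odds ratios are
exp(coefficient) with Wald 95% intervals exp(coef +/- 1.96 SE), the
convention of standard clinical statistics software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cohort, DrugClass, PatientRecord

__all__ = [
    "CovariateBins",
    "UnivariateResult",
    "LogisticFit",
    "SeparationError",
    "AliasedDesignError",
    "bin_covariates",
    "covariate_frame",
    "univariate_tests",
    "fit_logistic",
    "table7_report",
    "MODEL_COVARIATES",
    "REFERENCE_LEVELS",
]


AGE_BINS = ("0-17", "18-40", "41-60", ">=61")
LOS_BINS = ("1-10", "11-20", "21-30", ">=31")
BMI_BINS = ("<18.5", "18.5-23.9", ">=24.0")
PRIOR_HOSP_BINS = ("0-3", "4-6", ">=7")
ANTIFUNGAL_BINS = ("1", "2", "3")
ANTIBACTERIAL_BINS = ("0-3", "4-6", ">=7")
TRIGGER_BINS = ("0-2", "3-5", ">=6")
COMORBIDITY_BINS = ("1-3", "4-6", ">6")


@dataclass(frozen=True)
class CovariateBins:
    age_bin: str
    sex: str
    department: str
    los_bin: str
    bmi_bin: Optional[str]  # None when BMI is missing on the chart
    prior_hosp_bin: str
    antifungal_bin: str
    antibacterial_bin: str
    trigger_bin: str
    comorbidity_bin: str


def _cut(value: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    """Assign to the first bin whose upper edge is not exceeded."""
    for upper, label in zip(edges, labels):
        if value < upper:
            return label
    return labels[-1]


def bin_covariates(record: PatientRecord, n_triggers: int = 0) -> CovariateBins:
    """Deterministic binning of one admission's covariates.

    ``n_triggers`` is the number of distinct positive triggers found on
    screening (it is an outcome of screening, not a chart field, so it is
    passed in).  Boundary values fall in the bin whose printed label
    contains them; comorbidity counts of exactly 6 fall in "4-6" because the
    top bin is strictly ">6".
    """
    if n_triggers < 0:
        raise ValueError("n_triggers negative")
    d = record.demographics
    n_antifungal = sum(
        1 for o in record.orders if o.drug_class is DrugClass.antifungal
    )
    n_antibacterial = sum(
        1 for o in record.orders if o.drug_class is DrugClass.antibacterial
    )
    return CovariateBins(
        age_bin=_cut(d.age_years, (18, 41, 61), AGE_BINS),
        sex=d.sex.value,
        department=d.department.value,
        los_bin=_cut(record.length_of_stay_days, (11, 21, 31), LOS_BINS),
        bmi_bin=None if d.bmi is None else _cut(d.bmi, (18.5, 24.0), BMI_BINS),
        prior_hosp_bin=_cut(d.prior_hospitalizations, (4, 7), PRIOR_HOSP_BINS),
        antifungal_bin=ANTIFUNGAL_BINS[min(max(n_antifungal, 1), 3) - 1],
        antibacterial_bin=_cut(n_antibacterial, (4, 7), ANTIBACTERIAL_BINS),
        trigger_bin=_cut(n_triggers, (3, 6), TRIGGER_BINS),
        comorbidity_bin=_cut(record.comorbidity_count, (4, 7), COMORBIDITY_BINS),
    )


def covariate_frame(
    cohort: Cohort, trigger_counts: dict[str, int] | None = None
) -> pd.DataFrame:
    """Binned covariates for every admission, one row per patient."""
    trigger_counts = trigger_counts or {}
    rows = []
    for rec in cohort.records:
        bins = bin_covariates(rec, trigger_counts.get(rec.patient_id, 0))
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age_bin": bins.age_bin,
                "sex": bins.sex,
                "department": bins.department,
                "los_bin": bins.los_bin,
                "bmi_bin": bins.bmi_bin,
                "prior_hosp_bin": bins.prior_hosp_bin,
                "antifungal_bin": bins.antifungal_bin,
                "antibacterial_bin": bins.antibacterial_bin,
                "trigger_bin": bins.trigger_bin,
                "comorbidity_bin": bins.comorbidity_bin,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


@dataclass(frozen=True)
class UnivariateResult:
    covariate: str
    test: str  # "chi_square" or "rank_sum"
    statistic: float
    p_value: float


_CATEGORICAL = [
    "age_bin",
    "sex",
    "department",
    "los_bin",
    "bmi_bin",
    "prior_hosp_bin",
    "antifungal_bin",
    "antibacterial_bin",
    "trigger_bin",
    "comorbidity_bin",
]


def univariate_tests(
    cohort: Cohort,
    ade_patients: set[str],
    trigger_counts: dict[str, int] | None = None,
) -> list[UnivariateResult]:
    """Chi-square tests on each binned covariate and rank-sum tests on the
    underlying continuous variables, ADE vs no-ADE groups."""
    frame = covariate_frame(cohort, trigger_counts)
    outcome = frame.index.to_series().isin(ade_patients)
    if outcome.all() or not outcome.any():
        raise ValueError("both outcome groups must be non-empty")
    results: list[UnivariateResult] = []
    for cov in _CATEGORICAL:
        sub = frame[cov].dropna()
        table = pd.crosstab(sub, outcome.loc[sub.index])
        if table.shape[0] < 2:
            continue  # covariate constant in this cohort
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
        results.append(UnivariateResult(cov, "chi_square", float(chi2), float(p)))

    trigger_counts = trigger_counts or {}
    continuous = {
        "age_years": [r.demographics.age_years for r in cohort.records],
        "length_of_stay_days": [r.length_of_stay_days for r in cohort.records],
        "comorbidity_count": [r.comorbidity_count for r in cohort.records],
        "n_triggers": [
            trigger_counts.get(r.patient_id, 0) for r in cohort.records
        ],
    }
    mask = np.asarray(
        [r.patient_id in ade_patients for r in cohort.records], dtype=bool
    )
    for name, values in continuous.items():
        vals = np.asarray(values, dtype=float)
        a, b = vals[mask], vals[~mask]
        if len(np.unique(vals)) < 2:
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        results.append(UnivariateResult(name, "rank_sum", float(stat), float(p)))
    return results


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


class AliasedDesignError(ValueError):
    """The design matrix is rank-deficient; names the aliased terms."""


@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    overall_p: float
    deviance: float
    null_deviance: float
    converged: bool
    iterations: int
    deviance_path: list[float] = field(default_factory=list)
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "OR": self.odds_ratios,
                "ci_low": self.ci_lower,
                "ci_high": self.ci_upper,
                "p": self.p_values,
            }
        ).set_index("term")


#: Covariates entered in the multivariable model and their reference levels.
MODEL_COVARIATES = [
    "los_bin",
    "antifungal_bin",
    "antibacterial_bin",
    "trigger_bin",
    "comorbidity_bin",
]
REFERENCE_LEVELS = {
    "los_bin": "1-10",
    "antifungal_bin": "1",
    "antibacterial_bin": "0-3",
    "trigger_bin": "0-2",
    "comorbidity_bin": "1-3",
    "age_bin": "0-17",
    "sex": "male",
    "department": "internal",
    "bmi_bin": "18.5-23.9",
    "prior_hosp_bin": "0-3",
}


def _build_design(
    design: pd.DataFrame, reference_levels: dict[str, str]
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(design))]
    names = ["intercept"]
    for cov in design.columns:
        ref = reference_levels.get(cov)
        levels = [lv for lv in pd.unique(design[cov].dropna()) if lv != ref]
        levels = sorted(map(str, levels))
        if ref is not None and ref not in set(map(str, design[cov].dropna())):
            raise ValueError(f"reference level {ref!r} absent from {cov!r}")
        for lv in levels:
            cols.append((design[cov].astype(str) == lv).to_numpy(float))
            names.append(f"{cov}[{lv}]")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(rmat))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag < tol).any():
        # pivoted QR via scipy would name columns exactly; a greedy scan does
        # the same job for a handful of terms
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise AliasedDesignError(f"aliased terms in design: {aliased}")


def fit_logistic(
    design: pd.DataFrame,
    outcome: Iterable[int] | np.ndarray | pd.Series,
    reference_levels: dict[str, str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression via IRLS.

    ``design`` holds categorical covariates (one column each); dummy columns
    are built against ``reference_levels`` (defaults to the chart-review
    reference bins).  Convergence is declared when the maximum absolute
    score (gradient of the log-likelihood) falls below ``score_tol``.

    Raises :class:`AliasedDesignError` for rank-deficient designs and
    :class:`SeparationError` when the likelihood diverges (complete
    separation).
    """
    reference_levels = (
        REFERENCE_LEVELS if reference_levels is None else reference_levels
    )
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X, names = _build_design(design, reference_levels)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    _check_rank(X, names)

    beta = np.zeros(p)
    deviance_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        deviance_path.append(float(dev))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular weighted information matrix; fitted probabilities "
                "have collapsed to 0/1 (separation)"
            ) from exc
        # step-halving keeps the deviance monotone non-increasing
        new_beta = beta + step
        for _ in range(30):
            eta_n = X @ new_beta
            mu_n = np.clip(
                1.0 / (1.0 + np.exp(-np.clip(eta_n, -35, 35))), 1e-12, 1 - 1e-12
            )
            dev_n = -2.0 * np.sum(
                y * np.log(mu_n) + (1 - y) * np.log(1 - mu_n)
            )
            if dev_n <= dev + 1e-10:
                break
            new_beta = (beta + new_beta) / 2.0
        beta = new_beta
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverging (|beta| > 30): complete or "
                "quasi-complete separation in the design"
            )
    if not converged:
        raise SeparationError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g}); the design may be "
            "separated"
        )

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    fisher = X.T @ (X * w[:, None])
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    ci_low = np.exp(beta - 1.959963984540054 * se)
    ci_high = np.exp(beta + 1.959963984540054 * se)

    dev = deviance_path[-1]
    pbar = y.mean()
    null_dev = -2.0 * np.sum(
        y * np.log(pbar) + (1 - y) * np.log(1 - pbar)
    )
    overall_p = float(stats.chi2.sf(null_dev - dev, df=p - 1)) if p > 1 else 1.0

    return LogisticFit(
        terms=names,
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        ci_lower=ci_low,
        ci_upper=ci_high,
        p_values=p_values,
        overall_p=overall_p,
        deviance=float(dev),
        null_deviance=float(null_dev),
        converged=converged,
        iterations=it,
        deviance_path=deviance_path,
        fitted=mu,
    )


def table7_report(
    cohort: Cohort,
    ade_patients: set[str],
    trigger_counts: dict[str, int],
) -> pd.DataFrame:
    """Multivariable odds-ratio report in the standard chart-review layout.

    Fits the five-covariate model (length of stay, combined antifungals,
    combined antibacterials, positive triggers, comorbid diseases, each
    against its reference bin) and returns one row per level with OR, 95% CI
    and Wald p; reference levels carry OR 1 and blank CI.
    """
    frame = covariate_frame(cohort, trigger_counts)[MODEL_COVARIATES]
    outcome = frame.index.to_series().isin(ade_patients).astype(int).to_numpy()
    fit = fit_logistic(frame, outcome)
    by_term = fit.summary()
    level_order = {
        "los_bin": LOS_BINS,
        "antifungal_bin": ANTIFUNGAL_BINS,
        "antibacterial_bin": ANTIBACTERIAL_BINS,
        "trigger_bin": TRIGGER_BINS,
        "comorbidity_bin": COMORBIDITY_BINS,
    }
    rows = []
    for cov in MODEL_COVARIATES:
        ref = REFERENCE_LEVELS[cov]
        for lv in level_order[cov]:
            term = f"{cov}[{lv}]"
            if lv == ref:
                rows.append(
                    {"covariate": cov, "level": lv, "reference": True,
                     "OR": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                     "p": np.nan}
                )
            elif term in by_term.index:
                r = by_term.loc[term]
                rows.append(
                    {"covariate": cov, "level": lv, "reference": False,
                     "OR": float(r["OR"]), "ci_low": float(r["ci_low"]),
                     "ci_high": float(r["ci_high"]), "p": float(r["p"])}
                )
    return pd.DataFrame(rows)
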