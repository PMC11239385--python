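"""Covariate binning, univariate tests and the IRLS logistic regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from afgtt import Cohort, bin_covariates, fit_logistic, table7_report
from afgtt.risk_factors import (
    MODEL_COVARIATES,
    REFERENCE_LEVELS,
    AliasedDesignError,
    SeparationError,
    univariate_tests,
)
from afgtt.synthetic import simulate_logistic_cohort


class TestBinning:
    @pytest.mark.parametrize(
        "los, expected",
        [(1, "1-10"), (10, "1-10"), (11, "11-20"), (20, "11-20"),
         (21, "21-30"), (30, "21-30"), (31, ">=31"), (90, ">=31")],
    )
    def test_length_of_stay_edges(self, record_factory, los, expected):
        assert bin_covariates(record_factory(los=los)).los_bin == expected

    def test_comorbidity_six_in_middle_bin(self, record_factory):
        rec = record_factory().model_copy(update={"comorbidity_count": 6})
        assert bin_covariates(rec).comorbidity_bin == "4-6"
        rec7 = record_factory().model_copy(update={"comorbidity_count": 7})
        assert bin_covariates(rec7).comorbidity_bin == ">6"

    def test_zero_triggers_lowest_bin(self, record_factory):
        assert bin_covariates(record_factory(), n_triggers=0).trigger_bin == "0-2"
        assert bin_covariates(record_factory(), n_triggers=6).trigger_bin == ">=6"

    def test_missing_bmi_maps_to_none(self, record_factory):
        assert bin_covariates(record_factory(bmi=None)).bmi_bin is None

    def test_negative_trigger_count_rejected(self, record_factory):
        with pytest.raises(ValueError):
            bin_covariates(record_factory(), n_triggers=-1)


class TestUnivariate:
    def _cohort(self, record_factory, loss_by_group):
        recs = []
        i = 0
        for group, losses in loss_by_group.items():
            for los in losses:
                recs.append(record_factory(patient_id=f"{group}{i}", los=los))
                i += 1
        return Cohort(records=recs)

    def test_identical_group_distributions_give_zero_statistic(
        self, record_factory
    ):
        cohort = self._cohort(
            record_factory,
            {"A": [5] * 10 + [15] * 10, "B": [5] * 10 + [15] * 10},
        )
        ade = {r.patient_id for r in cohort.records if r.patient_id.startswith("A")}
        results = {r.covariate: r for r in univariate_tests(cohort, ade)}
        assert results["los_bin"].statistic == pytest.approx(0.0)

    def test_empty_group_rejected(self, record_factory):
        cohort = self._cohort(record_factory, {"A": [5, 15, 25, 35]})
        with pytest.raises(ValueError):
            univariate_tests(cohort, set())


class TestLogistic:
    def test_null_model_intercept_is_observed_logit(self):
        y = np.array([1] * 30 + [0] * 70)
        frame = pd.DataFrame(index=range(100))
        fit = fit_logistic(frame, y, reference_levels={})
        assert fit.coefficients[0] == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_recovers_known_log_odds_ratio(self):
        beta = {"intercept": -1.0, "trigger_bin[3-5]": 0.8}
        frame, y = simulate_logistic_cohort(beta, n=2000, seed=3,
                                            covariates=["trigger_bin"])
        fit = fit_logistic(frame, y)
        est = dict(zip(fit.terms, fit.coefficients))["trigger_bin[3-5]"]
        assert abs(est - 0.8) <= 0.15

    def test_matches_independent_likelihood_maximization(self):
        frame, y = simulate_logistic_cohort(
            {"intercept": -0.5, "comorbidity_bin[4-6]": 0.6}, n=600, seed=9,
            covariates=["comorbidity_bin", "los_bin"],
        )
        fit = fit_logistic(frame, y)
        X = np.column_stack(
            [np.ones(len(frame))]
            + [
                (frame[c] == lv).to_numpy(float)
                for c in frame.columns
                for lv in sorted(set(frame[c])) if lv != REFERENCE_LEVELS[c]
            ]
        )

        def negll(b):
            eta = X @ b
            return np.sum(np.logaddexp(0, eta)) - y @ eta

        def grad(b):
            mu = 1 / (1 + np.exp(-(X @ b)))
            return X.T @ (mu - y)

        res = optimize.minimize(
            negll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        # BFGS may stop with "precision loss" once the gradient is already
        # tiny; what matters for the oracle is the score at the solution
        assert np.max(np.abs(grad(res.x))) < 1e-6
        assert np.max(np.abs(np.sort(res.x) - np.sort(fit.coefficients))) < 1e-6

    def test_deviance_never_increases(self):
        frame, y = simulate_logistic_cohort(
            {"intercept": -1.0, "trigger_bin[>=6]": 2.0}, n=400, seed=21
        )
        fit = fit_logistic(frame, y)
        path = np.array(fit.deviance_path)
        assert np.all(np.diff(path) <= 1e-8)

    def test_mean_fitted_equals_prevalence(self):
        frame, y = simulate_logistic_cohort({"intercept": -0.8}, n=500, seed=2)
        fit = fit_logistic(frame, y)
        assert fit.fitted.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_or_and_ci_consistency(self):
        frame, y = simulate_logistic_cohort(
            {"intercept": -0.5, "los_bin[11-20]": 0.5}, n=800, seed=4,
            covariates=["los_bin"],
        )
        fit = fit_logistic(frame, y)
        assert np.allclose(fit.odds_ratios, np.exp(fit.coefficients))
        assert np.all(fit.ci_lower < fit.odds_ratios)
        assert np.all(fit.odds_ratios < fit.ci_upper)

    def test_aliased_design_named(self):
        n = 100
        rng = np.random.default_rng(0)
        a = rng.choice(["x", "y"], n)
        frame = pd.DataFrame({"cov_a": a, "cov_b": a})  # perfect alias
        y = rng.integers(0, 2, n)
        with pytest.raises(AliasedDesignError, match="cov_b"):
            fit_logistic(frame, y, reference_levels={"cov_a": "x", "cov_b": "x"})

    def test_complete_separation_detected(self):
        n = 80
        x = np.array(["lo"] * 40 + ["hi"] * 40)
        y = np.array([0] * 40 + [1] * 40)
        frame = pd.DataFrame({"cov": x})
        with pytest.raises(SeparationError):
            fit_logistic(frame, y, reference_levels={"cov": "lo"})

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame({"cov": ["a", "b"] * 10})
        with pytest.raises(ValueError):
            fit_logistic(frame, np.ones(20), reference_levels={"cov": "a"})


class TestReportShape:
    def test_fixture_report_layout(self, study, study_screen, study_ades):
        cohort, truth = study
        counts = {}
        for h in study_screen.hits:
            counts[h.patient_id] = counts.get(h.patient_id, 0) + 1
        report = table7_report(cohort, truth.ade_patients, counts)
        assert sorted(report["covariate"].unique()) == sorted(MODEL_COVARIATES)
        refs = report[report["reference"]]
        assert {
            (r.covariate, r.level) for r in refs.itertuples()
        } == {(c, REFERENCE_LEVELS[c]) for c in MODEL_COVARIATES}
        assert (refs["OR"] == 1.0).all()
        assert len(report) == 16  # 4 + 3 + 3 + 3 + 3 levels
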