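"""Cox partial-likelihood fitter: oracles, ties, inference, covariate selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from bicarotid import (
    SeparationError,
    cox_log_likelihood,
    fit_cox,
    select_covariates,
    wald_interval,
)


def brute_force_breslow_beta(time, event, x):
    """Independent 1-D oracle: direct evaluation of the Breslow partial likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)

    def negll(b):
        ll = 0.0
        for i in np.where(event == 1)[0]:
            risk = time >= time[i]
            ll += b * x[i] - math.log(np.sum(np.exp(b * x[risk])))
        return -ll

    res = minimize_scalar(negll, bounds=(-15, 15), method="bounded",
                          options={"xatol": 1e-12})
    return res.x


SMALL_INSTANCES = [
    # (times, events, x): tie-free, non-separated
    ((1, 2, 3, 4, 5, 6), (1, 1, 1, 1, 1, 1), (1, 0, 1, 0, 1, 0)),
    ((2, 1, 4, 3, 6, 5, 8, 7), (1, 0, 1, 1, 0, 1, 1, 1), (0, 1, 1, 0, 1, 0, 1, 0)),
    ((1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5),
     (1, 1, 0, 1, 1, 1, 0, 1, 1, 1), (1, 0, 0, 1, 1, 0, 1, 0, 1, 0)),
]


class TestOracle:
    @pytest.mark.parametrize("time,event,x", SMALL_INSTANCES)
    def test_matches_brute_force_maximizer(self, time, event, x):
        oracle = brute_force_breslow_beta(time, event, x)
        fit = fit_cox(np.asarray(time, float), event, np.asarray(x, float))
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("time,event,x", SMALL_INSTANCES)
    def test_loglik_agrees_with_hand_formula(self, time, event, x):
        fit = fit_cox(np.asarray(time, float), event, np.asarray(x, float))
        t = np.asarray(time, float)
        e = np.asarray(event, int)
        xv = np.asarray(x, float)
        b = fit.coef[0]
        ll = sum(
            b * xv[i] - math.log(np.sum(np.exp(b * xv[t >= t[i]])))
            for i in np.where(e == 1)[0]
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-10)

    def test_separated_data_detected(self):
        # all exposed subjects fail first: monotone likelihood
        with pytest.raises(SeparationError):
            fit_cox(np.arange(1.0, 7.0), np.ones(6, int), np.array([1., 1., 1., 0., 0., 0.]))


class TestFitProperties:
    def test_symmetric_groups_give_zero_coefficient(self):
        # two groups with mirrored event patterns
        time = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        event = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        fit = fit_cox(time, event, x)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(1)
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.binomial(1, 0.3, n).astype(float)})
        t = rng.exponential(1.0, n) * np.exp(-0.4 * X["a"])
        e = rng.binomial(1, 0.7, n)
        e[:3] = 1
        fb = fit_cox(t, e, X, ties="breslow")
        fe = fit_cox(t, e, X, ties="efron")
        np.testing.assert_allclose(fb.coef, fe.coef, atol=1e-10)

    def test_loglik_at_estimate_dominates_null(self, classified_small):
        from bicarotid import geometry_design
        men = classified_small[classified_small["sex"] == "M"]
        t, e, X = geometry_design(men, "R")
        fit = fit_cox(t, e, X)
        assert fit.loglik >= fit.loglik_null
        assert fit.gradient_norm < 1e-6

    def test_agrees_with_lifelines_reference(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = rng.exponential(1.0, n) * np.exp(-0.5 * X["a"] + 0.3 * X["b"])
        e = (t < np.quantile(t, 0.8)).astype(int)
        t = np.minimum(t, np.quantile(t, 0.8))
        t += rng.uniform(0, 1e-6, n)  # break the censoring-time ties
        fit = fit_cox(t, e, X)
        cph = lifelines.CoxPHFitter().fit(X.assign(T=t, E=e), "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-6)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["twice_a"] = 2 * X["a"]
        t = rng.exponential(1.0, 50)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_cox(t, np.ones(50, int), X)


class TestWaldInterval:
    def test_closed_form(self):
        fit = fit_cox(*_simple_data())
        fit.coef = np.array([0.0])
        fit.se = np.array([0.1])
        hr, lo, hi = wald_interval(fit, fit.terms[0])
        assert (round(hr, 2), round(lo, 2), round(hi, 2)) == (1.0, 0.82, 1.22)

    def test_absent_term(self):
        fit = fit_cox(*_simple_data())
        with pytest.raises(KeyError):
            wald_interval(fit, "nope")

    def test_oracle_curvature_on_small_instance(self):
        """SE agrees with a finite-difference Hessian of the hand-written likelihood."""
        time, event, x = SMALL_INSTANCES[0]
        time = np.asarray(time, float)
        x1 = np.asarray(x, float)
        fit = fit_cox(time, event, x1)
        b = fit.coef[0]
        h = 1e-4
        ll = lambda v: cox_log_likelihood([v], time, event, x1)
        second = (ll(b + h) - 2 * ll(b) + ll(b - h)) / h**2
        assert fit.se[0] == pytest.approx(1.0 / math.sqrt(-second), rel=1e-4)


def _simple_data():
    time = np.array([1, 2, 3, 4, 5, 6], float)
    event = np.array([1, 1, 0, 1, 1, 1])
    x = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]})
    return time, event, x


class TestCovariateSelection:
    @staticmethod
    def _cohort(n=4000, confounded=False, seed=17):
        rng = np.random.default_rng(seed)
        exposure = rng.binomial(1, 0.3, n).astype(float)
        noise = rng.normal(size=n)
        if confounded:
            # confounder drives both exposure and hazard
            conf = 0.8 * exposure + rng.normal(size=n)
            log_hr = 0.7 * exposure + 0.9 * conf
        else:
            conf = rng.normal(size=n)
            log_hr = 0.7 * exposure
        t = rng.exponential(1.0, n) / (0.05 * np.exp(log_hr))
        cens = rng.uniform(8, 12, n)
        e = (t <= cens).astype(int)
        time = np.minimum(t, cens)
        X = pd.DataFrame({"exposure": exposure, "candidate": conf, "noise": noise})
        return time, e, X

    def test_pure_noise_candidate_dropped(self):
        time, e, X = self._cohort(confounded=False)
        res = select_covariates(time, e, X, exposure_terms=["exposure"],
                                candidate_terms=["candidate", "noise"])
        assert "noise" not in res.retained
        assert any(s.action == "dropped" for s in res.audit)

    def test_confounder_retained_by_change_in_estimate(self):
        time, e, X = self._cohort(confounded=True)
        # alpha=0 makes every candidate droppable on significance alone, so
        # only the change-in-estimate rule can keep the confounder in
        full = select_covariates(time, e, X, exposure_terms=["exposure"],
                                 candidate_terms=["candidate"], alpha=0.0)
        assert "candidate" in full.retained
        kept = [s for s in full.audit if s.term == "candidate"]
        assert kept and kept[0].action == "kept" and kept[0].max_exposure_shift > 0.10

    def test_empty_candidate_set_returns_base_model(self):
        time, e, X = self._cohort()
        res = select_covariates(time, e, X[["exposure", "noise"]],
                                exposure_terms=["exposure"], base_terms=["noise"],
                                candidate_terms=[])
        assert res.retained == ["exposure", "noise"]
        assert res.audit == []

    def test_audit_trail_is_ordered_text(self):
        time, e, X = self._cohort()
        res = select_covariates(time, e, X, exposure_terms=["exposure"],
                                candidate_terms=["candidate", "noise"])
        txt = res.audit_text()
        assert all(line.split()[0] in {"DROPPED", "KEPT"} for line in txt.splitlines() if line)
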