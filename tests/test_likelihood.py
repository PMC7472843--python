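"""Partial-likelihood values, tie corrections, Newton fitting and the
Breslow baseline estimator."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from survcoxbench import SimulationConfig, fit_cox, simulate_dataset
from survcoxbench.cox.likelihood import (
    PartialLikelihood,
    breslow_cumulative_hazard,
    fit_newton,
)


def textbook_loglik(eta, times, status, ties):
    """Direct risk-set evaluation of both tie formulas (independent of the
    cumulative-sum implementation)."""
    eta = np.asarray(eta, float)
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    ll = 0.0
    for t in np.unique(times[status == 1]):
        tied = np.flatnonzero((times == t) & (status == 1))
        risk = np.flatnonzero(times >= t)
        S = np.exp(eta[risk]).sum()
        T = np.exp(eta[tied]).sum()
        d = len(tied)
        ll += eta[tied].sum()
        for l in range(d):
            ll -= np.log(S - (l / d) * T) if ties == "efron" else np.log(S)
    return ll


class TestPartialLoglik:
    def test_equal_risk_closed_form(self):
        pl = PartialLikelihood([1, 2, 3], [1, 1, 1])
        assert pl.loglik(np.zeros(3)) == pytest.approx(-np.log(6), abs=1e-12)

    def test_location_invariance(self, rng):
        times = rng.uniform(1, 10, 40)
        status = rng.integers(0, 2, 40)
        status[0] = 1
        eta = rng.normal(size=40)
        for ties in ("efron", "breslow"):
            pl = PartialLikelihood(times, status, ties)
            assert pl.loglik(eta) == pytest.approx(pl.loglik(eta + 7.3), abs=1e-10)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_tied_fixture_matches_textbook_formula(self, ties):
        times = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 8.0])
        status = np.array([1, 1, 0, 1, 1, 0])
        eta = np.array([0.5, -0.2, 0.1, 0.9, -0.4, 0.3])
        pl = PartialLikelihood(times, status, ties)
        assert pl.loglik(eta) == pytest.approx(
            textbook_loglik(eta, times, status, ties), abs=1e-12)

    def test_breslow_equals_efron_without_ties(self, rng):
        times = rng.uniform(1, 100, 60)  # continuous: no ties
        status = rng.integers(0, 2, 60)
        status[:5] = 1
        eta = rng.normal(size=60)
        lb = PartialLikelihood(times, status, "breslow").loglik(eta)
        le = PartialLikelihood(times, status, "efron").loglik(eta)
        assert lb == pytest.approx(le, abs=1e-12)

    def test_depends_only_on_time_status_multiset_at_null(self, rng):
        times = rng.uniform(1, 10, 30)
        status = rng.integers(0, 2, 30)
        status[0] = 1
        perm = rng.permutation(30)
        l1 = PartialLikelihood(times, status).loglik(np.zeros(30))
        l2 = PartialLikelihood(times[perm], status[perm]).loglik(np.zeros(30))
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_non_finite_eta_rejected(self):
        pl = PartialLikelihood([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="non-finite"):
            pl.loglik(np.array([0.0, np.inf, 0.0]))

    def test_gradient_matches_finite_differences(self, rng):
        times = rng.uniform(1, 10, 25)
        times[3] = times[7]  # introduce a tie
        status = rng.integers(0, 2, 25)
        status[[3, 7]] = 1
        eta = rng.normal(scale=0.5, size=25)
        for ties in ("breslow", "efron"):
            pl = PartialLikelihood(times, status, ties)
            _, grad = pl.loglik_grad(eta)
            for j in [0, 3, 7, 12]:
                e = np.zeros(25)
                e[j] = 1e-6
                fd = (pl.loglik(eta + e) - pl.loglik(eta - e)) / 2e-6
                assert grad[j] == pytest.approx(fd, abs=1e-5)

    def test_projected_hessian_matches_finite_differences(self, rng):
        times = rng.uniform(1, 10, 20)
        status = np.ones(20, dtype=int)
        W = rng.normal(size=(20, 3))
        beta = rng.normal(scale=0.3, size=3)
        pl = PartialLikelihood(times, status, "efron")
        _, grad, H = pl.loglik_grad_hess(W @ beta, W)
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1e-6
            _, gp, _ = pl.loglik_grad_hess(W @ (beta + e), W)
            fd = (gp - grad) / 1e-6
            np.testing.assert_allclose(-H[:, j], fd, atol=1e-4)


class TestNewtonFit:
    def test_matches_derivative_free_optimizer_1d(self, rng):
        times = rng.uniform(1, 10, 80)
        status = rng.integers(0, 2, 80)
        status[:8] = 1
        x = rng.normal(size=(80, 1))
        res = fit_newton(x, times, status)
        pl = PartialLikelihood(times, status)
        opt = minimize_scalar(lambda b: -pl.loglik(x[:, 0] * b),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-8})
        assert res.beta[0] == pytest.approx(opt.x, abs=1e-5)
        assert res.converged

    def test_consistency_two_group_exponential(self):
        # true log hazard ratio 0.7, no censoring
        rng = np.random.default_rng(77)
        n = 2000
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        res = fit_newton(x[:, None], t, np.ones(n, dtype=int))
        se = 1.0 / np.sqrt(res.neg_hessian[0, 0])
        assert abs(res.beta[0] - 0.7) < 3 * se

    def test_wald_coverage_under_null(self):
        # pure-noise covariate: 95% Wald interval covers 0 about 95% of runs
        rng = np.random.default_rng(55)
        n, reps = 500, 200
        covered = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 1))
            t = rng.exponential(size=n)
            res = fit_newton(x, t, np.ones(n, dtype=int))
            se = 1.0 / np.sqrt(res.neg_hessian[0, 0])
            covered += abs(res.beta[0]) < 1.96 * se
        assert 0.91 <= covered / reps <= 0.985

    def test_column_scaling_equivariance(self, rng):
        times = rng.uniform(1, 10, 100)
        status = rng.integers(0, 2, 100)
        status[:10] = 1
        X = rng.normal(size=(100, 2))
        r1 = fit_newton(X, times, status)
        Xs = X.copy()
        Xs[:, 0] *= 4.0
        r2 = fit_newton(Xs, times, status)
        assert r2.beta[0] == pytest.approx(r1.beta[0] / 4.0, abs=1e-6)
        assert r2.beta[1] == pytest.approx(r1.beta[1], abs=1e-6)

    def test_no_events_rejected(self, rng):
        with pytest.raises(ValueError, match="no events"):
            fit_newton(rng.normal(size=(10, 1)), rng.uniform(1, 2, 10),
                       np.zeros(10, dtype=int))

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate: coefficient diverges
        times = np.arange(1.0, 21.0)
        status = np.ones(20, dtype=int)
        x = np.linspace(1, -1, 20)[:, None]  # later death = lower x
        res = fit_newton(x, times, status, coef_cap=20.0)
        assert (not res.converged) or abs(res.beta[0]) > 10


class TestBreslowBaseline:
    def test_equal_risk_closed_form(self):
        t, H = breslow_cumulative_hazard(np.zeros(3), [1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(H, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1])

    def test_nondecreasing(self, rng):
        times = rng.uniform(1, 10, 50)
        status = rng.integers(0, 2, 50)
        status[:5] = 1
        _, H = breslow_cumulative_hazard(rng.normal(size=50), times, status)
        assert np.all(np.diff(H) >= 0) and H[0] >= 0

    def test_tracks_unit_exponential(self):
        ds, _ = simulate_dataset(SimulationConfig(
            n=2000, p=1, m=1, a_true=[0.5], genetic_variance=0.0,
            architecture="null", censoring=0.0, seed=3))
        fit = fit_cox(ds)
        bh = fit.baseline_hazard()
        for t0 in (0.2, 0.5, 1.0):
            assert bh.at(t0) == pytest.approx(t0, rel=0.15)
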