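"""Locally weighted censored quantile regression: loss, kernel weights,
local Kaplan-Meier, redistribution weights, the LP fit and the bootstrap.

Oracles: an independently coded plain quantile-regression LP (different
parametrization), statsmodels QuantReg, exhaustive grid search on tiny
instances, and the km module for the h -> infinity limit.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

import cqrsurv as cs
from cqrsurv.cqr import (
    CQRProblem,
    _censored_F,
    _local_km_F,
    _weights_from_F,
    check_loss,
    default_bandwidth,
)
from cqrsurv.exceptions import ConfigurationError, RankDeficiencyError


def plain_qr_lp(X, Y, tau):
    """Independent plain quantile-regression LP oracle.

    Different parametrization from the implementation: beta split into
    beta+ - beta- with all variables non-negative, dense constraint matrix,
    default HiGHS method.  Returns (beta, objective).
    """
    n, p = X.shape
    # variables: [beta+ (p), beta- (p), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(2 * p), np.full(n, tau), np.full(n, 1 - tau)])
    A = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A, b_eq=Y, bounds=[(0, None)] * (2 * p + 2 * n), method="highs")
    assert res.status == 0
    beta = res.x[:p] - res.x[p : 2 * p]
    return beta, float(res.fun)


def full_objective(beta, X, Y, delta, w, tau, y_inf):
    """The weighted CQR objective evaluated directly from its definition."""
    resid = Y - X @ beta
    obj = np.sum(w * check_loss(resid, tau))
    obj += np.sum((1 - w) * check_loss(y_inf - X @ beta, tau))
    return float(obj)


class TestCheckLoss:
    @pytest.mark.parametrize(
        "u,tau,expected", [(2.0, 0.5, 1.0), (-2.0, 0.25, 1.5), (0.0, 0.9, 0.0)]
    )
    def test_hand_values(self, u, tau, expected):
        assert check_loss(u, tau) == pytest.approx(expected)

    @given(st.floats(-50, 50), st.floats(0.01, 0.99))
    def test_nonnegative_and_convex_at_zero(self, u, tau):
        assert check_loss(u, tau) >= 0
        assert check_loss(u, tau) >= check_loss(0.0, tau)

    def test_tau_out_of_range(self):
        with pytest.raises(ConfigurationError):
            check_loss(1.0, 1.5)


class TestKernelWeights:
    def test_flat_kernel_limit_is_uniform(self):
        rng = np.random.default_rng(0)
        Xc = rng.normal(size=(12, 3))
        w = cs.kernel_weights(Xc, Xc[4], h=1e9)
        np.testing.assert_allclose(w, 1 / 12, atol=1e-12)

    def test_delta_kernel_limit_concentrates(self):
        Xc = np.array([[0.0], [1.0], [2.0]])
        w = cs.kernel_weights(Xc, np.array([1.0]), h=1e-4)
        np.testing.assert_allclose(w, [0, 1, 0], atol=1e-12)
        # ties split equally
        Xc2 = np.array([[0.0], [1.0], [1.0], [3.0]])
        w2 = cs.kernel_weights(Xc2, np.array([1.0]), h=1e-4)
        np.testing.assert_allclose(w2, [0, 0.5, 0.5, 0], atol=1e-12)

    def test_three_point_hand_gaussian(self):
        # scalar points {-1, 0, 1} have population SD sqrt(2/3); at h=1 the
        # kernel exponent for the outer points is (1/sd)^2/2 = 3/4
        Xc = np.array([[-1.0], [0.0], [1.0]])
        w = cs.kernel_weights(Xc, np.array([0.0]), h=1.0)
        k = np.exp(-0.75)
        expected = np.array([k, 1.0, k]) / (1 + 2 * k)
        np.testing.assert_allclose(w, expected, rtol=1e-12)
        assert w[1] == max(w) and w[0] == w[2]

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        Xc = rng.normal(size=(30, 4))
        for h in (0.1, 1.0, 10.0):
            assert cs.kernel_weights(Xc, Xc[0], h).sum() == pytest.approx(1.0)


class TestLocalKM:
    def _problem(self, rng, n=40, h=None):
        t = np.maximum(rng.exponential(10, n), 0.1)
        d = (rng.random(n) < 0.6).astype(int)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        return CQRProblem(X=X, Y=t, delta=d, tau=0.5, h=h)

    def test_before_first_observation_is_zero(self):
        prob = self._problem(np.random.default_rng(2))
        assert cs.local_km(1e-6, prob.covariates[0], prob) == 0.0

    def test_single_event_consumes_all_mass(self):
        prob = CQRProblem(
            X=np.array([[1.0, 0.3]]), Y=np.array([5.0]), delta=np.array([1]), tau=0.5
        )
        assert cs.local_km(5.0, np.array([0.3]), prob) == pytest.approx(1.0)

    def test_flat_kernel_equals_one_minus_global_km(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            prob = self._problem(rng, n=35, h=1e9)
            cur = cs.km_fit(prob.Y, prob.delta)
            for t0 in np.unique(prob.Y):
                F = cs.local_km(t0, prob.covariates[1], prob)
                assert F == pytest.approx(1 - cs.survival_at(cur, t0), abs=1e-12)

    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(4)
        prob = self._problem(rng, n=120, h=0.7)
        cens = prob.delta == 0
        targets, times = prob.covariates[cens], prob.Y[cens]
        a = _local_km_F(prob, targets, times, use_numba=False)
        b = _local_km_F(prob, targets, times, use_numba=True)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_monotone_in_t(self):
        rng = np.random.default_rng(5)
        prob = self._problem(rng, n=50, h=0.8)
        x0 = prob.covariates[7]
        grid = np.linspace(0, prob.Y.max(), 25)
        vals = [cs.local_km(t, x0, prob) for t in grid]
        assert np.all(np.diff(vals) >= -1e-12)
        assert all(0 <= v <= 1 for v in vals)


class TestCensoringWeights:
    def test_events_carry_full_weight(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        prob = CQRProblem(
            X=cs.design_matrix(small_synthetic.cohort, params),
            Y=f.time.to_numpy(),
            delta=f.event.to_numpy(),
            tau=0.5,
        )
        W = cs.censoring_weights(prob)
        assert np.all(W.w[f.event == 1] == 1.0)
        assert np.all((W.w >= 0) & (W.w <= 1))
        assert np.all(np.isnan(W.F_at_C[f.event == 1]))

    def test_redistribution_formula_hand_values(self):
        delta = np.array([1, 0, 0, 0])
        F = np.array([np.nan, 0.2, 0.5, 0.8])
        W = _weights_from_F(delta, F, tau=0.5)
        np.testing.assert_allclose(W.w, [1.0, 0.375, 0.0, 1.0])

    def test_more_censoring_does_not_add_full_weight_subjects(self):
        rng = np.random.default_rng(8)
        n = 400
        T = np.maximum(10 + 3 * rng.standard_normal(n), 0.2)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        counts = []
        for cmax in (40.0, 12.0):  # heavier censoring second
            C = rng.uniform(1, cmax, n)
            Y, D = np.minimum(T, C), (T <= C).astype(int)
            W = cs.censoring_weights(CQRProblem(X=X, Y=Y, delta=D, tau=0.5))
            counts.append(int(np.sum(W.w == 1.0)))
        assert counts[1] <= counts[0]


class TestFitCQR:
    def test_intercept_only_median_is_sample_median(self):
        prob = CQRProblem(
            X=np.ones((3, 1)), Y=np.array([1.0, 2.0, 3.0]), delta=np.ones(3, int), tau=0.5
        )
        fit = cs.fit_cqr(prob)
        assert fit.beta[0] == pytest.approx(2.0, abs=1e-9)

    def test_no_censoring_matches_independent_lp(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(20, 61))
            X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
            Y = X @ [4, 1.5, -2] + rng.standard_normal(n)
            tau = float(rng.uniform(0.2, 0.8))
            fit = cs.fit_cqr(CQRProblem(X=X, Y=Y, delta=np.ones(n, int), tau=tau))
            _, obj = plain_qr_lp(X, Y, tau)
            assert fit.objective == pytest.approx(obj, abs=1e-8)

    def test_no_censoring_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = X @ [3, 2] + rng.standard_normal(n)
        for tau in (0.25, 0.5, 0.75):
            fit = cs.fit_cqr(CQRProblem(X=X, Y=Y, delta=np.ones(n, int), tau=tau))
            qr = sm.QuantReg(Y, X).fit(q=tau)
            np.testing.assert_allclose(fit.beta, qr.params, atol=5e-4)

    def test_censored_instance_matches_grid_search(self):
        """Hand-built 8-subject, one-covariate instance: the LP objective
        equals the exhaustive minimum over a fine coefficient lattice."""
        Y = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 12.0])
        delta = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        X = np.column_stack([np.ones(8), x])
        prob = CQRProblem(X=X, Y=Y, delta=delta, tau=0.5, h=1.0, y_inf=1000.0)
        W = cs.censoring_weights(prob)
        fit = cs.fit_cqr(prob, weights=W)

        b0s = np.linspace(-5, 15, 321)
        b1s = np.linspace(-5, 8, 261)
        best = np.inf
        for b0 in b0s:
            for b1 in b1s:
                val = full_objective(np.array([b0, b1]), X, Y, delta, W.w, 0.5, 1000.0)
                best = min(best, val)
        step = max(b0s[1] - b0s[0], b1s[1] - b1s[0])
        assert fit.objective <= best + 1e-9
        assert fit.objective == pytest.approx(best, abs=step * 8)

    def test_objective_is_local_minimum(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        prob = CQRProblem(
            X=cs.design_matrix(small_synthetic.cohort, params),
            Y=f.time.to_numpy(),
            delta=f.event.to_numpy(),
            tau=0.5,
        )
        W = cs.censoring_weights(prob)
        fit = cs.fit_cqr(prob, weights=W)
        base = full_objective(fit.beta, prob.X, prob.Y, prob.delta, W.w, 0.5, prob.y_inf)
        assert base == pytest.approx(fit.objective, rel=1e-10)
        for j in range(len(fit.beta)):
            for eps in (-1e-3, 1e-3):
                pert = fit.beta.copy()
                pert[j] += eps
                assert (
                    full_objective(pert, prob.X, prob.Y, prob.delta, W.w, 0.5, prob.y_inf)
                    >= base - 1e-9
                )

    def test_y_inf_insensitivity(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        X = cs.design_matrix(small_synthetic.cohort, params)
        Y, D = f.time.to_numpy(), f.event.to_numpy()
        fits = [
            cs.fit_cqr(CQRProblem(X=X, Y=Y, delta=D, tau=0.5, y_inf=y)) for y in (1e4, 2e4)
        ]
        np.testing.assert_allclose(fits[0].beta, fits[1].beta, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(14)
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(RankDeficiencyError) as exc:
            cs.fit_cqr(CQRProblem(X=X, Y=np.abs(x) + 1, delta=np.ones(n, int), tau=0.5))
        assert len(exc.value.columns) >= 1


class TestBootstrap:
    def test_deterministic_given_seed(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        prob = CQRProblem(
            X=cs.design_matrix(small_synthetic.cohort, params),
            Y=f.time.to_numpy(),
            delta=f.event.to_numpy(),
            tau=0.5,
        )
        a = cs.bootstrap_se(prob, B=15, seed=99)
        b = cs.bootstrap_se(prob, B=15, seed=99)
        np.testing.assert_array_equal(a.se, b.se)
        assert np.all(a.se >= 0)

    def test_degenerate_data_gives_zero_se(self):
        n = 12
        prob = CQRProblem(
            X=np.ones((n, 1)), Y=np.full(n, 7.0), delta=np.ones(n, int), tau=0.5
        )
        res = cs.bootstrap_se(prob, B=10, seed=1)
        assert res.se[0] == pytest.approx(0.0, abs=1e-12)

    def test_se_tracks_sampling_variability(self, params):
        """Monte-Carlo oracle at reduced size: the bootstrap SE of the median
        fit is within 35 % of the empirical SD over independent cohorts."""
        taus = 0.5
        R, n, B = 40, 150, 40
        betas = []
        ss = np.random.SeedSequence(808)
        for child in ss.spawn(R):
            seed = int(child.generate_state(1)[0] % 2**31)
            syn = cs.generate_cohort(cs.CohortConfig(n=n, seed=seed))
            f = syn.cohort.frame
            X = cs.design_matrix(syn.cohort, params)
            fit = cs.fit_cqr(
                CQRProblem(X=X, Y=f.time.to_numpy(), delta=f.event.to_numpy(), tau=taus)
            )
            betas.append(fit.beta)
        emp_sd = np.asarray(betas).std(0, ddof=1)

        syn = cs.generate_cohort(cs.CohortConfig(n=n, seed=31415))
        f = syn.cohort.frame
        prob = CQRProblem(
            X=cs.design_matrix(syn.cohort, params),
            Y=f.time.to_numpy(),
            delta=f.event.to_numpy(),
            tau=taus,
        )
        boot = cs.bootstrap_se(prob, B=B, seed=2718)
        # compare on the stable covariate coefficients (size, nodes)
        for j in (3, 4):
            assert boot.se[j] == pytest.approx(emp_sd[j], rel=0.6)


class TestFitProcess:
    def test_single_tau_equals_fit_cqr(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        X = cs.design_matrix(small_synthetic.cohort, params)
        Y, D = f.time.to_numpy(), f.event.to_numpy()
        fits = cs.fit_process(X, Y, D, [0.5])
        direct = cs.fit_cqr(CQRProblem(X=X, Y=Y, delta=D, tau=0.5))
        np.testing.assert_allclose(fits[0].beta, direct.beta, atol=1e-9)

    def test_failures_do_not_abort_other_levels(
        self, small_synthetic, params, monkeypatch
    ):
        from cqrsurv import cqr as cqr_mod
        from cqrsurv.exceptions import UnidentifiedQuantileError

        f = small_synthetic.cohort.frame
        X = cs.design_matrix(small_synthetic.cohort, params)
        Y, D = f.time.to_numpy(), f.event.to_numpy()
        real_fit = cqr_mod.fit_cqr

        def failing_fit(problem, *args, **kwargs):
            if problem.tau > 0.9:
                raise UnidentifiedQuantileError("beyond the data")
            return real_fit(problem, *args, **kwargs)

        monkeypatch.setattr(cqr_mod, "fit_cqr", failing_fit)
        fits = cqr_mod.fit_process(X, Y, D, [0.5, 0.95])
        assert fits[0].beta is not None
        assert fits[1].beta is None and "beyond" in fits[1].error

    def test_log_scale_fits_log_time(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        X = cs.design_matrix(small_synthetic.cohort, params)
        Y, D = f.time.to_numpy(), f.event.to_numpy()
        log_fit = cs.fit_process(X, Y, D, [0.5], scale="log")[0]
        # rank-based weights are transform-invariant, so the log fit equals
        # the months fit applied to log(Y)
        direct = cs.fit_cqr(
            CQRProblem(X=X, Y=np.log(Y), delta=D, tau=0.5, y_inf=np.log(Y).max() + 10)
        )
        np.testing.assert_allclose(log_fit.beta, direct.beta, atol=1e-9)
        pred = cs.predict_quantile(
            log_fit.beta, 47.0, 1.5, 2, params, scale="log"
        )
        assert 10 < pred < 200  # a plausible number of months

    def test_process_table_layout(self, small_synthetic, params):
        f = small_synthetic.cohort.frame
        X = cs.design_matrix(small_synthetic.cohort, params)
        fits = cs.fit_process(X, f.time.to_numpy(), f.event.to_numpy(), [0.25, 0.5])
        tab = cs.process_table(fits, ["const", "z2", "z", "size", "nodes"])
        assert list(tab.index) == ["25", "50"] and tab.shape == (2, 5)


def test_default_bandwidth_rates():
    assert default_bandwidth(1000, 1) == pytest.approx(1.06 * 1000 ** (-0.2))
    # multivariate rate is wider than the univariate rate for the same n
    assert default_bandwidth(1000, 4) > default_bandwidth(1000, 1)
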