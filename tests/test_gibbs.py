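import numpy as np
import pytest
from scipy import stats

from gnbfactor.gibbs import (
    gibbs_sweep,
    run_gibbs,
    update_beta,
    update_delta,
    update_dispersion,
    update_h,
    update_pg,
    update_phi,
    update_precisions,
    update_theta,
)
from gnbfactor.model import (
    CountMatrix,
    CovariateSet,
    Hyperparams,
    ModelState,
    compute_psi,
    simulate_counts,
)


def _state(V, J, P=1, Q=1, K=1, rng=None, **over):
    rng = rng or np.random.default_rng(0)
    fields = dict(
        r=np.ones(J), beta=np.zeros((V, P)), delta=np.zeros((J, Q)),
        phi=rng.standard_normal((V, K)) * 0.3, theta=rng.standard_normal((J, K)) * 0.3,
        alpha=np.ones(P), eta=np.ones(Q), gamma=np.ones(K), h=1.0,
    )
    fields.update(over)
    return ModelState(**fields)


class TestDispersionUpdate:
    def test_no_data_recovers_prior(self, rng):
        # n = 0 everywhere and psi -> -inf: posterior collapses to Gamma(e0, rate h)
        J = 50_000
        hyper = Hyperparams(e0=2.0, f0=1.0, K=1)
        state = _state(1, J)
        n = np.zeros((1, J), dtype=np.int64)
        psi = np.full((1, J), -30.0)
        ell = update_dispersion(n, state, psi, hyper, rng)
        assert np.all(ell == 0)
        # softplus(-30) ~ 1e-13, so rate ~ h = 1
        assert state.r.mean() == pytest.approx(2.0, rel=0.05)
        assert state.r.var(ddof=1) == pytest.approx(2.0, rel=0.1)

    def test_rate_accumulates_log1mp_over_genes(self, rng):
        # V=10 genes at p=0.5: rate = h - 10 ln(0.5) = h + 10 ln 2
        V, J = 10, 200_000
        hyper = Hyperparams(e0=1.0, f0=1.0, K=1)
        state = _state(V, J, h=2.0)
        n = np.zeros((V, J), dtype=np.int64)
        psi = np.zeros((V, J))
        update_dispersion(n, state, psi, hyper, rng)
        rate = 2.0 + 10.0 * np.log(2.0)
        assert state.r.mean() == pytest.approx(hyper.e0 / rate, rel=0.02)

    def test_tables_bounded_by_counts(self, rng):
        V, J = 8, 12
        state = _state(V, J, r=np.full(12, 0.8))
        n = rng.poisson(4.0, size=(V, J))
        ell = update_dispersion(n, state, np.zeros((V, J)), Hyperparams(K=1), rng)
        assert np.all(ell <= n)
        assert np.all(ell[n == 0] == 0)
        assert np.all(state.r > 0)


class TestPgUpdate:
    def test_mean_and_shape(self, rng):
        V, J = 1, 50_000
        state = _state(V, J, r=np.full(J, 2.0))
        n = np.full((V, J), 3, dtype=np.int64)
        psi = np.ones((V, J))
        omega = update_pg(n, state, psi, rng)
        assert omega.shape == (V, J)
        # E[PG(5, 1)] = (5/2) tanh(1/2)
        assert omega.mean() == pytest.approx(2.5 * np.tanh(0.5), rel=0.01)
        assert np.all(omega > 0)


class TestCoefficientUpdates:
    def test_beta_prior_recovery_when_design_is_zero(self, rng):
        V, J = 30_000, 3
        state = _state(V, J, alpha=np.array([4.0]))
        cov = CovariateSet(X=np.zeros((J, 1)), Z=np.ones((V, 1)))
        omega = np.full((V, J), 0.7)
        n = np.ones((V, J), dtype=np.int64)
        update_beta(n, state, omega, cov, rng)
        assert state.beta.mean() == pytest.approx(0.0, abs=0.02)
        assert state.beta.var(ddof=1) == pytest.approx(0.25, rel=0.05)

    def test_delta_prior_recovery_when_design_is_zero(self, rng):
        V, J = 3, 30_000
        state = _state(V, J, eta=np.array([0.25]))
        cov = CovariateSet(X=np.ones((J, 1)), Z=np.zeros((V, 1)))
        omega = np.full((V, J), 0.7)
        n = np.ones((V, J), dtype=np.int64)
        update_delta(n, state, omega, cov, rng)
        assert state.delta.var(ddof=1) == pytest.approx(4.0, rel=0.05)

    def test_phi_prior_recovery_when_scores_are_zero(self, rng):
        V, J, K = 30_000, 3, 2
        state = _state(V, J, K=K, theta=np.zeros((J, K)))
        cov = CovariateSet.build(V, J)
        omega = np.full((V, J), 0.5)
        update_phi(np.ones((V, J), dtype=np.int64), state, omega, cov, rng)
        assert state.phi.var(ddof=1) == pytest.approx(1.0, rel=0.05)

    def test_theta_prior_recovery_when_loadings_are_zero(self, rng):
        V, J, K = 3, 30_000, 1
        state = _state(V, J, K=K, phi=np.zeros((V, K)), gamma=np.array([2.0]))
        cov = CovariateSet.build(V, J)
        omega = np.full((V, J), 0.5)
        update_theta(np.ones((V, J), dtype=np.int64), state, omega, cov, rng)
        assert state.theta.var(ddof=1) == pytest.approx(0.5, rel=0.05)

    def test_concentration_limit_shrinks_posterior_variance(self, rng):
        # huge omega -> covariance -> 0 -> draws concentrate at the mean
        # (zero factors and n = r make the posterior mean exactly 0)
        V, J = 2_000, 4
        state = _state(V, J, phi=np.zeros((V, 1)), theta=np.zeros((J, 1)))
        cov = CovariateSet(X=np.ones((J, 1)), Z=np.ones((V, 1)))
        omega = np.full((V, J), 1e8)
        n = np.ones((V, J), dtype=np.int64)
        update_beta(n, state, omega, cov, rng)
        assert state.beta.var(ddof=1) < 1e-6

    def test_beta_delta_transposition_symmetry(self):
        """Transposing data and swapping (X, beta, alpha) <-> (Z, delta, eta)
        must reproduce the same draws from the same rng stream."""
        rng1 = np.random.default_rng(77)
        rng2 = np.random.default_rng(77)
        V, J, P = 7, 5, 2
        master = np.random.default_rng(3)
        n = master.poisson(2.0, size=(V, J))
        omega = master.gamma(1.0, 1.0, size=(V, J)) + 0.05
        X = master.standard_normal((J, P))
        state = ModelState(
            r=np.full(J, 1.3), beta=master.standard_normal((V, P)),
            delta=master.standard_normal((J, P)), phi=master.standard_normal((V, 2)),
            theta=master.standard_normal((J, 2)), alpha=np.array([1.0, 2.0]),
            eta=np.array([1.0, 2.0]), gamma=np.ones(2), h=1.0,
        )
        cov = CovariateSet(X=X, Z=master.standard_normal((V, P)))
        # direct delta update
        direct = state.copy()
        update_delta(n, direct, omega, cov, rng1)
        # transposed problem: cells become genes; r is constant so the
        # pseudo-data (n - r)/2 transposes cleanly
        trans = ModelState(
            r=np.full(V, 1.3), beta=state.delta.copy(), delta=state.beta.copy(),
            phi=state.theta.copy(), theta=state.phi.copy(), alpha=state.eta,
            eta=state.alpha, gamma=state.gamma, h=1.0,
        )
        cov_t = CovariateSet(X=cov.Z, Z=cov.X)
        update_beta(n.T, trans, omega.T, cov_t, rng2)
        np.testing.assert_allclose(trans.beta, direct.delta, rtol=1e-10)


class TestPrecisionUpdates:
    def test_zero_coefficients_recover_prior_with_count_only_shape(self, rng):
        V, J, P = 40, 30, 1
        hyper = Hyperparams(e0=0.5, f0=0.25, K=2)
        state = _state(V, J, P=P, K=2, theta=np.zeros((J, 2)), delta=np.zeros((J, 1)))
        draws = []
        for _ in range(4000):
            s = state.copy()
            update_precisions(s, hyper, rng)
            draws.append(s.alpha[0])
        draws = np.asarray(draws)
        shape = hyper.e0 + V / 2.0
        assert draws.mean() == pytest.approx(shape / hyper.f0, rel=0.05)

    def test_two_gene_arithmetic_example(self, rng):
        # V=2, beta column = (1, 1), e0=f0=0.01: Gamma(1.01, rate 1.01), mean 1
        hyper = Hyperparams(e0=0.01, f0=0.01, K=1)
        state = _state(2, 3, beta=np.ones((2, 1)))
        draws = np.empty(20_000)
        for i in range(draws.size):
            s = state.copy()
            update_precisions(s, hyper, rng)
            draws[i] = s.alpha[0]
        assert draws.mean() == pytest.approx(1.0, rel=0.03)
        assert draws.var(ddof=1) == pytest.approx(1.01 / 1.01**2, rel=0.06)

    def test_h_gamma_gamma_example(self, rng):
        # J=3, r=(1,1,1), e0=f0=0.01 -> Gamma(0.04, rate 3.01)
        hyper = Hyperparams(e0=0.01, f0=0.01, K=1)
        state = _state(2, 3, r=np.ones(3))
        draws = np.empty(50_000)
        for i in range(draws.size):
            s = state.copy()
            update_h(s, hyper, rng)
            draws[i] = s.h
        # relative MC error of a Gamma(0.04) mean at 5e4 draws is ~2%
        assert draws.mean() == pytest.approx(0.04 / 3.01, rel=0.1)
        assert np.all(draws > 0)


class TestRunGibbs:
    @pytest.fixture(scope="class")
    def small_fit(self):
        rng = np.random.default_rng(12)
        from gnbfactor.evaluation import moderate_ground_truth

        truth, cov = moderate_ground_truth(40, 25, 2, rng)
        counts = simulate_counts(truth, cov, rng)
        trace = run_gibbs(counts, cov, Hyperparams(K=2), n_iter=120, burn_in=60, seed=5)
        return counts, cov, trace

    def test_seeded_runs_are_bitwise_identical(self, small_fit):
        counts, cov, trace = small_fit
        repeat = run_gibbs(counts, cov, Hyperparams(K=2), n_iter=120, burn_in=60, seed=5)
        np.testing.assert_array_equal(trace.log_likelihood, repeat.log_likelihood)
        np.testing.assert_array_equal(trace.point_estimate.theta, repeat.point_estimate.theta)

    def test_point_estimate_is_post_burn_in_argmax(self, small_fit):
        _, _, trace = small_fit
        post = trace.log_likelihood[trace.burn_in :]
        assert trace.point_estimate_iteration >= trace.burn_in
        idx = trace.point_estimate_iteration
        assert trace.log_likelihood[idx] == post.max()

    def test_positivity_invariants_after_every_sweep(self, small_fit):
        _, _, trace = small_fit
        for state in trace.states[::10]:
            assert np.all(state.r > 0)
            assert np.all(state.alpha > 0) and np.all(state.eta > 0)
            assert np.all(state.gamma > 0) and state.h > 0

    def test_loglik_not_systematically_decreasing_after_burn_in(self, small_fit):
        _, _, trace = small_fit
        post = trace.log_likelihood[trace.burn_in :]
        res = stats.linregress(np.arange(post.size), post)
        # slope must not be significantly negative
        assert (res.slope >= 0) or (res.slope / res.stderr > -3.0)

    def test_trace_has_requested_length_and_thinning(self):
        counts = CountMatrix(np.random.default_rng(0).poisson(1.0, size=(10, 8)))
        trace = run_gibbs(counts, None, Hyperparams(K=1), n_iter=30, burn_in=10, seed=1, thin=3)
        assert len(trace) == 10

    def test_invalid_iteration_settings(self):
        counts = CountMatrix(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="n_iter"):
            run_gibbs(counts, None, Hyperparams(K=1), n_iter=10, burn_in=10)

    def test_covariate_shape_mismatch(self):
        counts = CountMatrix(np.ones((3, 3), dtype=int))
        bad = CovariateSet(X=np.ones((5, 1)), Z=np.ones((3, 1)))
        with pytest.raises(ValueError, match="covariate"):
            run_gibbs(counts, bad, Hyperparams(K=1), n_iter=4, burn_in=1)
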