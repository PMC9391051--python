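"""MV mixture core: likelihood, posteriors, initialisation, factor
M-step and EM."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from phenomv.mixture import (
    FactorCovariance,
    MixtureParams,
    em_fit,
    fa_objective,
    fit_factor_covariance,
    initialize_sigma,
    marginal_loglik,
    marginal_loglik_table,
    mv_estimates,
    posterior,
    random_init_sigma,
)
from phenomv.simulate import SimSpec, simulate_uv, symmetrized_kl
from phenomv.tables import RunConfig, UVResultTable

from conftest import make_params


def _single_params(tau2=1.0, P=1, omega=1.0):
    sig = FactorCovariance(W=np.zeros((P, 1)), psi=np.full(P, tau2))
    return MixtureParams(sigmas=[sig], pi=np.array([[1.0]]),
                         omega=np.array([omega]), R=np.eye(P))


class TestMarginalLoglik:
    def test_scalar_closed_form(self):
        # theta-hat = 0, prior var 1, noise var 1 -> N(0 | 0, 2)
        params = _single_params()
        got = marginal_loglik(np.array([0.0]), np.array([1.0]), params)
        assert got == pytest.approx(-0.5 * np.log(4 * np.pi), abs=1e-12)

    def test_equal_weight_mixture_is_average_density(self, rng):
        P = 3
        params = make_params(P=P, M=2, S=1, seed=1)
        params.pi = np.array([[0.5], [0.5]])
        est = rng.normal(size=P)
        se = 0.3 + rng.random(P)
        sig = params.sigmas[0].full()
        dens = [
            multivariate_normal.logpdf(
                est, mean=np.zeros(P),
                cov=om * sig + np.diag(se) @ params.R @ np.diag(se))
            for om in params.omega
        ]
        expected = logsumexp(dens) - np.log(2.0)
        got = marginal_loglik(est, se, params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_fully_missing_row_errors(self, arbitrary_params):
        with pytest.raises(ValueError, match="no observed"):
            marginal_loglik(np.array([np.nan] * 3), np.array([np.nan] * 3),
                            arbitrary_params)


class TestPosterior:
    def test_ridge_shrinkage_limit(self):
        # M=S=1, R=I, Sigma = tau^2 I, common noise sigma: classic ridge
        tau2, sigma = 2.0, 0.5
        P = 3
        params = _single_params(tau2=tau2, P=P)
        est = np.array([1.0, -2.0, 0.5])
        se = np.full(P, sigma)
        post = posterior(est, se, params)
        shrink = tau2 / (tau2 + sigma ** 2)
        np.testing.assert_allclose(post.mean, shrink * est, atol=1e-12)

    def test_perfect_correlation_imputes_missing(self):
        # unit variances, correlation ~1: the missing phenotype inherits
        # the observed one's posterior mean
        W = np.array([[1.0], [1.0]])
        sig = FactorCovariance(W=W, psi=np.full(2, 1e-8))
        params = MixtureParams(sigmas=[sig], pi=np.array([[1.0]]),
                               omega=np.array([1.0]), R=np.eye(2))
        est = np.array([1.5, np.nan])
        se = np.array([0.5, np.nan])
        post = posterior(est, se, params)
        assert post.mean[1] == pytest.approx(post.mean[0], rel=1e-6)

    def test_mixture_moments_match_monte_carlo(self, rng):
        # importance-sampling oracle on a 3-phenotype, M=2, S=2 fixture
        # with one missing phenotype
        params = make_params(P=3, M=2, S=2, seed=4, rho_R=0.2)
        est = np.array([0.8, -0.4, np.nan])
        se = np.array([0.5, 0.7, np.nan])
        post = posterior(est, se, params)
        n = 200_000
        flat_pi = params.pi.reshape(-1)
        comp = rng.choice(flat_pi.size, size=n, p=flat_pi)
        m_i, s_i = np.unravel_index(comp, params.pi.shape)
        th = np.empty((n, 3))
        for s in range(2):
            L = np.linalg.cholesky(params.sigmas[s].full())
            for m in range(2):
                idx = (m_i == m) & (s_i == s)
                th[idx] = (np.sqrt(params.omega[m])
                           * (L @ rng.standard_normal((3, idx.sum())))).T
        obs = [0, 1]
        Sg = np.diag(se[obs])
        Ni = np.linalg.inv(Sg @ params.R[np.ix_(obs, obs)] @ Sg)
        resid = est[obs][None] - th[:, obs]
        logw = -0.5 * np.einsum("np,pq,nq->n", resid, Ni, resid)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mc_mean = w @ th
        ess = 1.0 / np.sum(w ** 2)
        mc_se = np.sqrt(np.einsum("n,np->p", w, (th - mc_mean) ** 2) / ess)
        np.testing.assert_array_less(np.abs(post.mean - mc_mean), 3 * mc_se)

    def test_posterior_consistent_with_marginal(self, rng):
        params = make_params(P=4, M=3, S=1, seed=5)
        est = rng.normal(size=4)
        est[2] = np.nan
        se = 0.3 + rng.random(4)
        se[2] = np.nan
        post = posterior(est, se, params)
        assert post.log_evidence == pytest.approx(
            marginal_loglik(est, se, params), abs=1e-10)
        assert post.r.sum() == pytest.approx(1.0, abs=1e-10)


class TestInitialisation:
    def test_single_subset_is_zero_filled_sample_cov(self, small_uv):
        out = initialize_sigma(small_uv, S=1)
        X = np.nan_to_num(small_uv.estimate, nan=0.0).T
        expected = np.cov(X, rowvar=False, ddof=1)
        if np.linalg.eigvalsh(expected).min() <= 0:
            expected = expected + 0.05 * np.eye(2)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_hand_computed_two_line_case(self):
        uv = UVResultTable(
            phenotypes=["p1", "p2"], lines=["g1", "g2"],
            centre_of_line={"g1": "C1", "g2": "C1"},
            estimate=np.array([[1.0, -1.0], [np.nan, np.nan]]),
            se=np.array([[0.5, 0.5], [np.nan, np.nan]]),
            is_null_line=np.array([False, False]))
        out = initialize_sigma(uv, S=1, eps_jitter=0.05)
        np.testing.assert_allclose(
            out[0], np.array([[2.05, 0.0], [0.0, 0.05]]), atol=1e-12)

    def test_positive_definite_across_random_fixtures(self, rng):
        for _ in range(100):
            P, G = rng.integers(2, 6), rng.integers(3, 12)
            est = rng.normal(size=(P, G))
            mask = rng.random((P, G)) < 0.3
            est[mask] = np.nan
            se = np.full((P, G), 0.5)
            se[mask] = np.nan
            keep = ~np.isnan(est).all(axis=0)
            if keep.sum() < 2:
                continue
            uv = UVResultTable(
                phenotypes=[f"p{i}" for i in range(P)],
                lines=[f"g{j}" for j in range(int(keep.sum()))],
                centre_of_line={f"g{j}": "C1"
                                for j in range(int(keep.sum()))},
                estimate=est[:, keep], se=se[:, keep],
                is_null_line=np.zeros(int(keep.sum()), dtype=bool))
            out = initialize_sigma(uv, S=1)
            assert np.linalg.eigvalsh(out[0]).min() > 0

    def test_random_init_scalar_mean_and_determinism(self):
        rng = np.random.default_rng(9)
        draws = np.array([random_init_sigma(1, rng)[0, 0]
                          for _ in range(10_000)])
        # Inverse-Wishart(I, nu) scalar mean 1/(nu - 2)
        mean, se = draws.mean(), draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(mean - 1.0 / 1998.0) < 3 * se
        a = random_init_sigma(4, np.random.default_rng(7))
        b = random_init_sigma(4, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)
        assert np.allclose(a, a.T) and np.linalg.eigvalsh(a).min() > 0


class TestFactorCovarianceFit:
    def test_self_fit_reaches_saturated_objective(self, rng):
        W = rng.normal(size=(5, 2))
        psi = 0.4 + rng.random(5)
        C = W @ W.T + np.diag(psi)
        fc = fit_factor_covariance(C, K=2)
        target = np.linalg.slogdet(C)[1] + 5
        assert fa_objective(fc.full(), C) <= target + 1e-4

    def test_fit_improves_with_rank(self, rng):
        A = rng.normal(size=(6, 6))
        C = A @ A.T + np.eye(6)
        err = {}
        for K in (1, 5):
            fc = fit_factor_covariance(C, K)
            err[K] = np.linalg.norm(fc.full() - C)
        assert err[5] < err[1]

    def test_factor_fit_beats_diagonal_only(self, rng):
        A = rng.normal(size=(3, 3))
        C = A @ A.T + 0.5 * np.eye(3)
        fc = fit_factor_covariance(C, K=1)
        diag_obj = fa_objective(np.diag(np.diag(C)), C)
        assert fa_objective(fc.full(), C) <= diag_obj + 1e-10

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            fit_factor_covariance(np.array([[1.0, 0.5], [0.2, 1.0]]), K=1)


class TestEMFit:
    def test_objective_trace_nondecreasing(self, rng):
        for trial in range(5):
            spec = SimSpec(P=5, G=80, K_true=2, M_true=2,
                           null_fraction=0.0, seed=100 + trial)
            uv, _ = simulate_uv(spec)
            cfg = RunConfig(K=2, omega_ladder=(0.5, 2.0), N_tra=80,
                            eps_tol=1e-6, seed=trial)
            _, state = em_fit(uv, cfg, np.eye(5), max_iter=40)
            trace = np.asarray(state.objective_trace)
            assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_single_component_first_pass_matches_closed_form(self):
        # S=1, M=1, no missing data, R=I, common noise: the first
        # moment-matrix update has the conjugate-normal closed form
        rng = np.random.default_rng(21)
        P, G, s0 = 4, 50, 0.6
        est = rng.normal(size=(P, G))
        uv = UVResultTable(
            phenotypes=[f"p{i}" for i in range(P)],
            lines=[f"g{j}" for j in range(G)],
            centre_of_line={f"g{j}": "C1" for j in range(G)},
            estimate=est, se=np.full((P, G), s0),
            is_null_line=np.zeros(G, dtype=bool))
        cfg = RunConfig(K=2, omega_ladder=(1.0,), N_tra=G, seed=0)
        init = initialize_sigma(uv, S=1)
        _, state = em_fit(uv, cfg, np.eye(P), init=init, max_iter=1)
        # the EM projects the initial covariance into factor form before
        # the first E-step
        sig0 = fit_factor_covariance(init[0], K=2).full()
        Kmat = sig0 + s0 ** 2 * np.eye(P)
        gain = sig0 @ np.linalg.inv(Kmat)
        V = sig0 - gain @ sig0
        mu = gain @ est  # (P, G) posterior means
        expected = V + (mu @ mu.T) / G
        np.testing.assert_allclose(state.C[0], expected, atol=1e-10)

    def test_parameter_recovery_from_model_data(self):
        spec = SimSpec(P=10, G=2000, K_true=3, M_true=3,
                       null_fraction=0.0, seed=2)
        uv, _ = simulate_uv(spec)
        cfg = RunConfig(K=3, omega_ladder=tuple(spec.omega_true),
                        N_tra=2000, seed=2)
        params, state = em_fit(uv, cfg, np.eye(10))
        assert symmetrized_kl(params.sigma_full()[0],
                              spec.sigma_true()[0]) < 0.5
        assert np.abs(params.pi - spec.pi_true).max() < 0.1

    def test_consistency_trend_in_sample_size(self):
        errs = {}
        for G in (500, 5000):
            spec = SimSpec(P=6, G=G, K_true=2, M_true=2,
                           null_fraction=0.0, seed=33)
            uv, _ = simulate_uv(spec)
            cfg = RunConfig(K=2, omega_ladder=tuple(spec.omega_true),
                            N_tra=G, seed=33)
            params, _ = em_fit(uv, cfg, np.eye(6))
            errs[G] = np.linalg.norm(params.sigma_full()[0]
                                     - spec.sigma_true()[0])
        assert errs[5000] < errs[500]


@pytest.fixture(scope="module")
def fitted():
    spec = SimSpec(P=8, G=400, K_true=3, M_true=3, null_fraction=0.2,
                   n_centres=2, n_procedures=2,
                   missing_blocks=[("C2", "PR1")], seed=6)
    uv, truth = simulate_uv(spec)
    cfg = RunConfig(K=3, omega_ladder=tuple(
        SimSpec(M_true=3).materialise(
            np.random.default_rng(0)).omega_true), N_tra=400, seed=6)
    params, _ = em_fit(uv, cfg, np.eye(8))
    return uv, truth, params


class TestMVEstimates:
    def test_posterior_sd_below_prior_sd(self, fitted):
        uv, _, params = fitted
        theta_mv, sd_mv = mv_estimates(uv, params)
        prior_sd = np.sqrt(np.diag(params.prior_cov()))
        assert np.all(sd_mv <= prior_sd[:, None] + 1e-10)
        assert np.isfinite(theta_mv).all()

    def test_matches_posterior_cell_by_cell(self, fitted):
        uv, _, params = fitted
        theta_mv, sd_mv = mv_estimates(uv, params)
        for g in [0, 5, 17]:
            post = posterior(uv.estimate[:, g], uv.se[:, g], params)
            np.testing.assert_allclose(theta_mv[:, g], post.mean,
                                       atol=1e-10)
            np.testing.assert_allclose(sd_mv[:, g], post.sd, atol=1e-10)

    def test_diagonal_prior_gives_zero_at_missing_cells(self):
        sig = FactorCovariance(W=np.zeros((3, 1)), psi=np.ones(3))
        params = MixtureParams(sigmas=[sig], pi=np.array([[1.0]]),
                               omega=np.array([1.0]), R=np.eye(3))
        est = np.array([[2.0], [np.nan], [1.0]])
        se = np.array([[0.5], [np.nan], [0.5]])
        uv = UVResultTable(["p1", "p2", "p3"], ["g1"], {"g1": "C1"},
                           est, se, np.array([False]))
        theta_mv, _ = mv_estimates(uv, params)
        assert theta_mv[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_shrinkage_relative_to_uv(self):
        # strong cross-phenotype correlation: posterior SDs should beat
        # the UV standard errors in the vast majority of observed cells
        rng = np.random.default_rng(55)
        P = 6
        W = np.ones((P, 1)) * 1.5
        spec = SimSpec(P=P, G=600, K_true=1, M_true=3, null_fraction=0.0,
                       W_true=[W], Psi_true=[np.full(P, 0.2)], seed=55)
        uv, _ = simulate_uv(spec)
        cfg = RunConfig(K=1, omega_ladder=tuple(spec.omega_true),
                        N_tra=600, seed=55)
        params, _ = em_fit(uv, cfg, np.eye(P))
        theta_mv, sd_mv = mv_estimates(uv, params)
        obs = uv.observed_mask
        frac_sd = np.mean(sd_mv[obs] < uv.se[obs])
        frac_shrunk = np.mean(np.abs(theta_mv[obs])
                              <= np.abs(uv.estimate[obs]))
        assert frac_sd > 0.9
        assert frac_shrunk > 0.5

    def test_loglik_table_matches_single_line(self, fitted, rng):
        uv, _, params = fitted
        table = marginal_loglik_table(uv, params)
        for g in rng.choice(uv.n_lines, 3, replace=False):
            assert table[g] == pytest.approx(
                marginal_loglik(uv.estimate[:, g], uv.se[:, g], params),
                abs=1e-10)
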