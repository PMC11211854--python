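import numpy as np
import pytest
from scipy import stats

from copulacci import (
    CopulaParams,
    SimConfig,
    SpatialGraph,
    copula_log_density,
    distributional_transform,
    fit_copula,
    fit_marginal_mu,
    likelihood_shape_screen,
    pair_log_likelihood,
    poisson_cdf,
    sample_copula_counts,
    selfloop_graph,
)
from copulacci.copula import gaussian_scores


class TestPoissonCdf:
    def test_negative_x_is_zero(self):
        assert poisson_cdf(-1, 3.7) == 0.0

    def test_small_case_matches_pmf_summation(self):
        # oracle: P(X<=1) = e^-2 (1 + 2) = 3 e^-2
        assert poisson_cdf(1, 2.0) == pytest.approx(3 * np.exp(-2), abs=1e-12)

    def test_far_upper_tail_is_one(self):
        assert poisson_cdf(10**6, 2.0) == pytest.approx(1.0, abs=1e-15)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            poisson_cdf(1, 0.0)


class TestMarginalMu:
    def test_closed_form_matches_numeric_maximization(self):
        counts = np.array([0, 1, 2])
        depths = np.array([100.0, 100.0, 100.0])
        mu = fit_marginal_mu(counts, depths)
        assert mu == pytest.approx(np.log(0.01), abs=1e-12)
        # numeric oracle: maximize the Poisson log-likelihood directly
        grid = np.linspace(mu - 0.5, mu + 0.5, 2001)
        ll = [stats.poisson.logpmf(counts, depths * np.exp(m)).sum() for m in grid]
        assert abs(grid[int(np.argmax(ll))] - mu) < 1e-3

    def test_rate_one_per_umi(self):
        d = np.array([10.0, 20.0, 30.0])
        assert fit_marginal_mu(d.astype(int), d) == pytest.approx(0.0, abs=1e-14)

    def test_multiplicity_scale_invariance(self):
        counts = np.array([0, 1, 4])
        depths = np.array([50.0, 80.0, 120.0])
        m = np.array([1.0, 2.0, 3.0])
        assert fit_marginal_mu(counts, depths, m) == pytest.approx(
            fit_marginal_mu(counts, depths, 2 * m), abs=1e-14
        )

    def test_all_zero_counts_degenerate(self):
        assert np.isnan(fit_marginal_mu([0, 0], [10.0, 10.0]))


class TestDistributionalTransform:
    def test_zero_count_closed_form(self):
        lam = 1.7
        assert distributional_transform(0, lam) == pytest.approx(np.exp(-lam) / 2, abs=1e-14)

    def test_vanishing_rate_limit_is_half(self):
        u = distributional_transform(0, 1e-14)
        assert u == pytest.approx(0.5, abs=1e-10)

    def test_monotone_in_count(self):
        for lam in (0.1, 1.0, 5.0, 50.0):
            u = distributional_transform(np.arange(0, 40), lam)
            assert np.all(np.diff(u) >= 0)
            assert np.all((u > 0) & (u < 1))


class TestCopulaLogDensity:
    def test_independence_copula_is_zero(self, rng):
        u, v = rng.uniform(0.01, 0.99, size=(2, 20))
        np.testing.assert_allclose(copula_log_density(u, v, 0.0), 0.0, atol=1e-14)

    def test_center_value_closed_form(self):
        assert copula_log_density(0.5, 0.5, 0.5) == pytest.approx(
            -0.5 * np.log(0.75), abs=1e-12
        )

    def test_matches_bivariate_normal_ratio_oracle(self, rng):
        for rho in (-0.9, -0.3, 0.2, 0.7):
            u, v = rng.uniform(0.01, 0.99, size=(2, 50))
            z1, z2 = stats.norm.ppf(u), stats.norm.ppf(v)
            cov = [[1, rho], [rho, 1]]
            oracle = (
                stats.multivariate_normal.logpdf(np.column_stack([z1, z2]), cov=cov)
                - stats.norm.logpdf(z1)
                - stats.norm.logpdf(z2)
            )
            np.testing.assert_allclose(copula_log_density(u, v, rho), oracle, atol=1e-10)

    def test_boundary_arguments_rejected(self):
        with pytest.raises(ValueError):
            copula_log_density(0.0, 0.5, 0.2)
        with pytest.raises(ValueError):
            copula_log_density(0.5, 0.5, 1.0)


def _three_edge_fixture():
    g = SpatialGraph(3, np.array([(0, 1), (1, 2), (2, 0)]))
    l = np.array([2, 0, 5])
    r = np.array([1, 3, 0])
    depths = np.array([100.0, 150.0, 80.0])
    return g, l, r, depths


class TestPairLogLikelihood:
    def test_rho_zero_reduces_to_independent_poisson(self):
        g, l, r, depths = _three_edge_fixture()
        params = CopulaParams(0.0, -3.5, -4.0)
        ll = pair_log_likelihood(g, l, r, depths, params)
        lam_l = depths * np.exp(params.mu_l)
        lam_r = depths * np.exp(params.mu_r)
        oracle = sum(
            stats.poisson.logpmf(l[i], lam_l[i]) + stats.poisson.logpmf(r[j], lam_r[j])
            for i, j in g.edges
        )
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_term_by_term_hand_oracle(self):
        g, l, r, depths = _three_edge_fixture()
        params = CopulaParams(0.4, -3.5, -4.0)
        lam_l = depths * np.exp(params.mu_l)
        lam_r = depths * np.exp(params.mu_r)
        oracle = 0.0
        for i, j in g.edges:  # explicit per-edge summation
            u = distributional_transform(l[i], lam_l[i])
            v = distributional_transform(r[j], lam_r[j])
            oracle += (
                stats.poisson.logpmf(l[i], lam_l[i])
                + stats.poisson.logpmf(r[j], lam_r[j])
                + copula_log_density(u, v, params.rho)
            )
        assert pair_log_likelihood(g, l, r, depths, params) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_invariant_to_edge_order(self, rng):
        g, l, r, depths = _three_edge_fixture()
        params = CopulaParams(-0.3, -3.0, -3.0)
        shuffled = SpatialGraph(3, g.edges[rng.permutation(3)])
        assert pair_log_likelihood(g, l, r, depths, params) == pytest.approx(
            pair_log_likelihood(shuffled, l, r, depths, params), abs=1e-12
        )

    def test_empty_edge_set_errors(self):
        g = SpatialGraph(3, np.empty((0, 2)))
        with pytest.raises(ValueError):
            pair_log_likelihood(g, [1, 0, 2], [0, 1, 1], [10.0] * 3, CopulaParams(0, -1, -1))


class TestFitCopula:
    def test_recovers_simulated_rho(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=500, rho=0.5, seed=11))
        fit = fit_copula(selfloop_graph(500), l, r, d)
        assert abs(fit.rho - 0.5) < 0.15
        assert not fit.screened_out

    def test_independent_data_near_zero(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=500, rho=0.0, seed=21))
        fit = fit_copula(selfloop_graph(500), l, r, d)
        assert abs(fit.rho) < 0.1

    def test_agrees_with_dense_grid_search(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=300, rho=-0.6, seed=31))
        g = selfloop_graph(300)
        fit = fit_copula(g, l, r, d)
        grid = np.arange(-0.999, 0.9991, 0.001)
        ll = [
            pair_log_likelihood(g, l, r, d, CopulaParams(rho, fit.params.mu_l, fit.params.mu_r))
            for rho in grid
        ]
        rho_grid = grid[int(np.argmax(ll))]
        assert abs(fit.rho - rho_grid) <= 0.0015  # within one grid step

    def test_ligand_receptor_swap_symmetry(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=200, rho=0.4, seed=41))
        g = SpatialGraph(200, np.column_stack([np.arange(200), np.arange(200)]))
        fit = fit_copula(g, l, r, d)
        fit_swapped = fit_copula(g, r, l, d)  # self-loop reversal is identity
        assert fit_swapped.rho == pytest.approx(fit.rho, abs=1e-4)

    def test_sign_flip_of_latent_scores(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=500, rho=0.6, seed=51))
        l2, r2, d2 = sample_copula_counts(SimConfig(n_samples=500, rho=-0.6, seed=51))
        fit_pos = fit_copula(selfloop_graph(500), l, r, d)
        fit_neg = fit_copula(selfloop_graph(500), l2, r2, d2)
        assert fit_pos.rho > 0.3 and fit_neg.rho < -0.3

    def test_all_zero_ligand_degenerate(self):
        g = selfloop_graph(4)
        fit = fit_copula(g, [0, 0, 0, 0], [1, 0, 2, 1], [10.0] * 4)
        assert fit.screened_out and fit.screen_reason == "degenerate"


class TestLikelihoodShapeScreen:
    def test_concave_profile_kept_default_excluded_literal(self):
        """A well-expressed pair has a strictly concave profile: the default
        polarity keeps it, the literal reading of the screen excludes it."""
        l, r, d = sample_copula_counts(SimConfig(n_samples=400, rho=0.3, seed=61))
        g = selfloop_graph(400)
        mu_l = fit_marginal_mu(l, d)
        mu_r = fit_marginal_mu(r, d)
        keep_default, detail = likelihood_shape_screen(g, l, r, d, mu_l, mu_r)
        keep_literal, _ = likelihood_shape_screen(g, l, r, d, mu_l, mu_r, mode="literal")
        assert keep_default
        assert not keep_literal
        assert detail["max_second_diff"] < 0

    def test_low_sparsity_simulated_pair_kept(self):
        l, r, d = sample_copula_counts(SimConfig(n_samples=500, rho=0.5, seed=71))
        assert float((l == 0).mean()) < 0.2
        fit = fit_copula(selfloop_graph(500), l, r, d)
        assert not fit.screened_out


class TestRectangleProbabilityOracle:
    """The distributional-transform likelihood approximates the exact
    discrete copula likelihood (rectangle probabilities from the copula CDF
    at the four corners of each count cell) and is maximized at a nearby
    correlation."""

    def _fixture(self):
        n = 10
        depths = np.full(n, 1000)
        mu = np.log(4 / 1000)  # per-spot rate 4: a non-sparse pair
        cfg = SimConfig(n_samples=n, rho=0.5, mu_l=mu, mu_r=mu, depths=depths, seed=3)
        l, r, d = sample_copula_counts(cfg)
        return l, r, d.astype(float), mu

    @staticmethod
    def _exact_loglik(l, r, lam, rho):
        from scipy import special

        cov = [[1, rho], [rho, 1]]

        def C(a, b, lm):
            ua = stats.poisson.cdf(a, lm) if a >= 0 else 0.0
            ub = stats.poisson.cdf(b, lm) if b >= 0 else 0.0
            if ua <= 0 or ub <= 0:
                return 0.0
            za = special.ndtri(min(ua, 1 - 1e-15))
            zb = special.ndtri(min(ub, 1 - 1e-15))
            return stats.multivariate_normal.cdf([za, zb], cov=cov)

        tot = 0.0
        for li, ri, lm in zip(l, r, lam):
            p = (
                C(li, ri, lm) - C(li - 1, ri, lm)
                - C(li, ri - 1, lm) + C(li - 1, ri - 1, lm)
            )
            tot += np.log(max(p, 1e-300))
        return tot

    def test_dt_likelihood_close_and_argmax_nearby(self):
        l, r, d, mu = self._fixture()
        g = selfloop_graph(10)
        lam = d * np.exp(mu)
        grid = np.arange(-0.6, 0.6001, 0.005)
        exact = np.array([self._exact_loglik(l, r, lam, rho) for rho in grid])
        dt = np.array([
            pair_log_likelihood(g, l, r, d, CopulaParams(rho, mu, mu)) for rho in grid
        ])
        assert np.abs(exact - dt).max() < 0.5  # small DT-approximation gap
        assert abs(grid[exact.argmax()] - grid[dt.argmax()]) < 0.05


class TestGaussianLimit:
    def test_dt_scores_standard_normal_at_large_rate(self):
        """For large Poisson rates the distributional-transform Gaussian
        scores of simulated counts are approximately standard normal."""
        rng = np.random.default_rng(5)
        lam = 500.0
        counts = rng.poisson(lam, size=2000)
        z = gaussian_scores(counts, np.full(2000, lam), 0.0)
        assert abs(z.mean()) < 0.08
        assert abs(z.std() - 1) < 0.05
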