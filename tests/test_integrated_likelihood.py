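import numpy as np
import pytest
from scipy.stats import invgamma

from oracles import (
    dense_marginal_loglik,
    mc_marginal_loglik,
    quad_over_sigma2,
    random_grouped_design,
    random_spd,
)

from mlevidence.integrated_likelihood import (
    compute_sufficient_stats,
    conditional_posterior_linear,
    conditional_posterior_ml_general,
    conditional_posterior_ml_intercept,
    log_evidence_nig,
    loglik_full,
    loglik_integrated_linear,
    loglik_integrated_ml_general,
    loglik_integrated_ml_intercept,
    loglik_integrated_nig,
    nig_posterior,
    LatentEffects,
    SufficientStats,
    VariancePoint,
)
from mlevidence.model_spec import (
    CovarianceStructure,
    GaussianPrior,
    GroupedDesign,
    ModelSpec,
    NIGPrior,
    cov_from_param,
)


def empty_stats(d, m=0, J=1):
    return SufficientStats(
        n=0, d=d, m=m, J=J, n_j=np.zeros(J),
        Sxx=np.zeros((d, d)), Sxy=np.zeros(d), Syy=0.0,
        gx=np.zeros((J, d)), gy=np.zeros(J),
        Szz=np.zeros((J, m, m)) if m else None,
        Szy=np.zeros((J, m)) if m else None,
        Sxz=np.zeros((J, d, m)) if m else None)


class TestSufficientStats:
    def test_matches_naive_double_loop(self, small_design):
        stats = compute_sufficient_stats(small_design)
        d = small_design
        Sxx = sum(np.outer(x, x) for x in d.X)
        assert np.allclose(stats.Sxx, Sxx)
        assert np.allclose(stats.Sxy, sum(x * yi for x, yi in zip(d.X, d.y)))
        assert stats.Syy == pytest.approx(sum(yi ** 2 for yi in d.y))
        for j in range(d.J):
            rows = np.flatnonzero(d.group == j)
            assert np.allclose(stats.gx[j], d.X[rows].sum(axis=0))
            assert stats.gy[j] == pytest.approx(d.y[rows].sum())
            assert np.allclose(stats.Szz[j],
                               sum(np.outer(z, z) for z in d.Z[rows]))
            assert np.allclose(stats.Sxz[j],
                               sum(np.outer(x, z)
                                   for x, z in zip(d.X[rows], d.Z[rows])))

    def test_permutation_invariance(self, small_design, rng):
        stats = compute_sufficient_stats(small_design)
        perm = rng.permutation(small_design.n)
        permuted = small_design.permuted(perm)
        stats2 = compute_sufficient_stats(permuted)
        assert np.allclose(stats.Sxx, stats2.Sxx)
        assert stats.Syy == pytest.approx(stats2.Syy)
        # per-group blocks match after aligning the relabelled group order
        align = [permuted.group_labels.index(lab)
                 for lab in small_design.group_labels]
        assert np.allclose(stats.Szz, stats2.Szz[align])
        assert np.allclose(stats.gx, stats2.gx[align])


class TestConditionalPosteriors:
    def test_no_data_returns_prior(self):
        prior = GaussianPrior(np.array([1.0, -2.0]), np.diag([2.0, 3.0]))
        cond = conditional_posterior_linear(empty_stats(2), prior, 1.3)
        assert np.allclose(cond.mean, prior.mu)
        assert np.allclose(cond.precision, prior.precision())
        cond = conditional_posterior_ml_intercept(empty_stats(2), prior, 1.0, 0.5)
        assert np.allclose(cond.mean, prior.mu)

    def test_huge_noise_variance_washes_out_data(self, small_design):
        stats = compute_sufficient_stats(small_design)
        prior = GaussianPrior(np.array([0.5, -0.5]), np.eye(2))
        cond = conditional_posterior_linear(stats, prior, 1e12)
        assert np.allclose(cond.mean, prior.mu, atol=1e-6)

    def test_matches_textbook_closed_form(self, rng):
        # independent transcription: Stilde = (Sigma^-1 + X'X/s2)^-1, etc.
        design = random_grouped_design(rng, n=6, d=2, J=1)
        stats = compute_sufficient_stats(design)
        mu = rng.normal(size=2)
        Sigma = random_spd(rng, 2)
        s2 = 0.7
        cond = conditional_posterior_linear(stats, GaussianPrior(mu, Sigma), s2)
        Sinv = np.linalg.inv(Sigma)
        prec = Sinv + design.X.T @ design.X / s2
        mean = np.linalg.solve(prec, Sinv @ mu + design.X.T @ design.y / s2)
        assert np.allclose(cond.precision, prec)
        assert np.allclose(cond.mean, mean)

    def test_intercept_reduces_to_linear_at_zero_group_variance(self, small_design):
        stats = compute_sufficient_stats(small_design)
        prior = GaussianPrior(np.zeros(2), np.eye(2))
        a = conditional_posterior_ml_intercept(stats, prior, 0.8, 0.0)
        b = conditional_posterior_linear(stats, prior, 0.8)
        assert np.allclose(a.mean, b.mean)
        assert np.allclose(a.precision, b.precision)


class TestIntegratedLikelihoods:
    """Dense-marginal oracle: integrating beta (and eta) against Gaussian
    priors leaves y multivariate normal with an explicitly computable
    covariance; the closed forms must agree with its log density."""

    @pytest.mark.parametrize("trial", range(20))
    def test_linear_matches_dense_marginal(self, trial):
        rng = np.random.default_rng(100 + trial)
        d = int(rng.integers(1, 4))
        design = random_grouped_design(rng, n=int(rng.integers(4, 10)), d=d, J=2)
        stats = compute_sufficient_stats(design)
        mu, Sigma = rng.normal(size=d), random_spd(rng, d)
        s2 = float(rng.uniform(0.2, 3.0))
        ours = loglik_integrated_linear(stats, GaussianPrior(mu, Sigma), s2)
        oracle = dense_marginal_loglik(design, mu, Sigma, s2)
        assert ours == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("trial", range(20))
    def test_intercept_matches_dense_marginal(self, trial):
        rng = np.random.default_rng(200 + trial)
        design = random_grouped_design(rng, n=9, d=2, J=3)
        stats = compute_sufficient_stats(design)
        mu, Sigma = rng.normal(size=2), random_spd(rng, 2)
        s2y, s2e = float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.05, 1.5))
        ours = loglik_integrated_ml_intercept(
            stats, GaussianPrior(mu, Sigma), s2y, s2e)
        oracle = dense_marginal_loglik(design, mu, Sigma, s2y, s2e=s2e)
        assert ours == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("trial", range(20))
    def test_general_matches_dense_marginal(self, trial):
        rng = np.random.default_rng(300 + trial)
        design = random_grouped_design(rng, n=10, d=2, J=3, m=2)
        stats = compute_sufficient_stats(design)
        mu, Sigma = rng.normal(size=2), random_spd(rng, 2)
        struct = CovarianceStructure(kind="pair_correlation", m=2)
        nu = np.array([rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0),
                       rng.uniform(-0.8, 0.8)])
        s2y = float(rng.uniform(0.2, 2.0))
        Sig_eta, ok = cov_from_param(struct, nu)
        assert ok
        ours = loglik_integrated_ml_general(
            stats, GaussianPrior(mu, Sigma), struct, s2y, nu)
        oracle = dense_marginal_loglik(design, mu, Sigma, s2y, Sig_eta=Sig_eta)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_intercept_matches_monte_carlo(self, rng):
        design = random_grouped_design(rng, n=5, d=1, J=2)
        stats = compute_sufficient_stats(design)
        mu, Sigma = np.array([0.3]), np.array([[1.2]])
        ours = loglik_integrated_ml_intercept(
            stats, GaussianPrior(mu, Sigma), 0.6, 0.3)
        mc, se = mc_marginal_loglik(design, mu, Sigma, 0.6, rng,
                                    n_draws=1_000_000, s2e=0.3)
        assert abs(ours - mc) < 3 * se

    def test_single_observation_zero_covariate(self):
        y = np.array([0.7])
        design = GroupedDesign(y=y, X=np.zeros((1, 2)))
        stats = compute_sufficient_stats(design)
        prior = GaussianPrior(np.ones(2), np.eye(2))
        s2 = 0.9
        expected = -0.5 * (np.log(2 * np.pi * s2) + y[0] ** 2 / s2)
        assert loglik_integrated_linear(stats, prior, s2) == pytest.approx(expected)

    def test_empty_dataset_gives_exact_zero(self):
        prior = GaussianPrior(np.zeros(2), random_spd(np.random.default_rng(0), 2))
        nig = NIGPrior(3.0, 0.4, np.zeros(2), np.eye(2), gamma=5.0)
        assert loglik_integrated_linear(empty_stats(2), prior, 1.0) == 0.0
        assert loglik_integrated_nig(empty_stats(2), nig, 1.0) == 0.0
        assert loglik_integrated_ml_intercept(empty_stats(2), prior, 1.0, 1.0) == 0.0
        assert log_evidence_nig(empty_stats(2), nig) == 0.0

    def test_invalid_variances_signal_zero_probability(self, small_design):
        stats = compute_sufficient_stats(small_design)
        prior = GaussianPrior(np.zeros(2), np.eye(2))
        assert loglik_integrated_linear(stats, prior, -1.0) == -np.inf
        assert loglik_integrated_ml_intercept(stats, prior, 1.0, -0.1) == -np.inf
        struct = CovarianceStructure(kind="pair_correlation", m=2)
        assert loglik_integrated_ml_general(
            stats, prior, struct, 1.0, [1.0, 1.0, 1.7]) == -np.inf

    def test_scale_robustness_no_nans(self, small_design):
        stats = compute_sufficient_stats(small_design)
        prior = GaussianPrior(np.zeros(2), np.eye(2))
        for s2 in np.logspace(-6, 6, 25):
            for val in (
                loglik_integrated_linear(stats, prior, s2),
                loglik_integrated_ml_intercept(stats, prior, s2, s2 / 3),
            ):
                assert not np.isnan(val)

    def test_permutation_and_relabel_invariance(self, small_design, rng):
        stats = compute_sufficient_stats(small_design)
        prior = GaussianPrior(np.zeros(2), np.eye(2))
        perm = rng.permutation(small_design.n)
        stats_p = compute_sufficient_stats(small_design.permuted(perm))
        assert loglik_integrated_ml_intercept(
            stats, prior, 0.7, 0.2) == pytest.approx(
            loglik_integrated_ml_intercept(stats_p, prior, 0.7, 0.2), abs=1e-10)


class TestReductionChain:
    @pytest.mark.parametrize("trial", range(5))
    def test_general_to_intercept_to_linear(self, trial):
        rng = np.random.default_rng(400 + trial)
        design = random_grouped_design(rng, n=9, d=2, J=3)
        design_z1 = GroupedDesign(y=design.y, X=design.X,
                                  Z=np.ones((design.n, 1)), group=design.group)
        stats = compute_sufficient_stats(design)
        stats_z1 = compute_sufficient_stats(design_z1)
        prior = GaussianPrior(rng.normal(size=2), random_spd(rng, 2))
        s2y, s2e = float(rng.uniform(0.3, 2.0)), float(rng.uniform(0.05, 1.0))
        struct = CovarianceStructure(kind="diagonal", m=1)
        general = loglik_integrated_ml_general(stats_z1, prior, struct, s2y, [s2e])
        intercept = loglik_integrated_ml_intercept(stats, prior, s2y, s2e)
        linear = loglik_integrated_linear(stats, prior, s2y)
        assert general == pytest.approx(intercept, abs=1e-10)
        assert loglik_integrated_ml_intercept(
            stats, prior, s2y, 0.0) == pytest.approx(linear, abs=1e-10)
        # diagonal group variances -> 0 approaches the linear model
        tiny = loglik_integrated_ml_general(stats_z1, prior, struct, s2y, [1e-14])
        assert tiny == pytest.approx(linear, abs=1e-5)


class TestNIG:
    def test_identity_with_scaled_gaussian_prior(self, small_design, rng):
        stats = compute_sufficient_stats(small_design)
        Sigma = random_spd(rng, 2)
        nig = NIGPrior(3.0, 0.4, np.zeros(2), Sigma, gamma=5.0)
        for s2 in (0.3, 1.0, 4.0):
            direct = loglik_integrated_nig(stats, nig, s2)
            via_linear = loglik_integrated_linear(
                stats, GaussianPrior(np.zeros(2), 5.0 * s2 * Sigma), s2)
            assert direct == pytest.approx(via_linear, abs=1e-10)

    def test_evidence_matches_quadrature(self, small_design):
        stats = compute_sufficient_stats(small_design)
        nig = NIGPrior(3.0, 0.4, np.zeros(2), np.eye(2), gamma=5.0)
        logpost = lambda s2: (loglik_integrated_nig(stats, nig, s2)
                              + invgamma.logpdf(s2, nig.a, scale=nig.b))
        quad = quad_over_sigma2(logpost)
        assert log_evidence_nig(stats, nig) == pytest.approx(quad, abs=1e-8)

    def test_posterior_update_coherence(self, rng):
        # two sequential half-dataset updates == one full update
        design = random_grouped_design(rng, n=8, d=2, J=1)
        first = GroupedDesign(y=design.y[:4], X=design.X[:4])
        second = GroupedDesign(y=design.y[4:], X=design.X[4:])
        nig = NIGPrior(3.0, 0.4, np.zeros(2), random_spd(rng, 2), gamma=5.0)
        full = nig_posterior(compute_sufficient_stats(design), nig)
        half = nig_posterior(compute_sufficient_stats(first), nig)
        chained = nig_posterior(compute_sufficient_stats(second), half)
        assert chained.a == pytest.approx(full.a)
        assert chained.b == pytest.approx(full.b)
        assert np.allclose(chained.mu, full.mu)
        assert np.allclose(chained.Sigma, full.Sigma, atol=1e-10)

    def test_posterior_matches_direct_formulas_d1(self, rng):
        design = random_grouped_design(rng, n=6, d=1, J=1)
        stats = compute_sufficient_stats(design)
        sig0 = 2.0
        nig = NIGPrior(2.5, 0.8, np.zeros(1), np.array([[sig0]]))
        post = nig_posterior(stats, nig)
        x, y = design.X[:, 0], design.y
        prec = 1.0 / sig0 + x @ x
        muhat = (x @ y) / prec
        assert post.a == pytest.approx(2.5 + 3.0)
        assert post.mu[0] == pytest.approx(muhat)
        assert post.Sigma[0, 0] == pytest.approx(1.0 / prec)
        assert post.b == pytest.approx(0.8 + 0.5 * (y @ y - muhat ** 2 * prec))

    def test_zero_data_update_is_identity(self):
        nig = NIGPrior(3.0, 0.4, np.zeros(2), np.eye(2), gamma=5.0)
        assert nig_posterior(empty_stats(2), nig) is nig


class TestFullLoglik:
    def test_residuals_at_mode_of_unit_height_gaussian(self):
        n, d = 4, 2
        X = np.ones((n, d))
        beta = np.array([0.25, 0.25])
        y = X @ beta
        design = GroupedDesign(y=y, X=X)
        from mlevidence.model_spec import InverseGammaPrior
        spec = ModelSpec(kind="linear",
                         coef_prior=GaussianPrior(np.zeros(d), np.eye(d)),
                         noise_prior=InverseGammaPrior(3, 1))
        val = loglik_full(design, spec, beta, VariancePoint(1.0 / (2 * np.pi)))
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_single_observation_standard_normal(self):
        design = GroupedDesign(y=np.array([0.4]), X=np.zeros((1, 1)))
        from mlevidence.model_spec import InverseGammaPrior
        spec = ModelSpec(kind="linear",
                         coef_prior=GaussianPrior(np.zeros(1), np.eye(1)),
                         noise_prior=InverseGammaPrior(3, 1))
        from scipy.stats import norm
        val = loglik_full(design, spec, np.zeros(1), VariancePoint(1.0))
        assert val == pytest.approx(norm.logpdf(0.4))

    def test_mc_over_eta_recovers_integrated_intercept(self, rng):
        # marginalise eta by Monte Carlo at fixed beta and compare with the
        # eta-integrated density implied by the closed form at Sigma -> 0
        design = random_grouped_design(rng, n=6, d=1, J=2)
        from mlevidence.model_spec import InverseGammaPrior
        spec = ModelSpec(kind="multilevel_intercept",
                         coef_prior=GaussianPrior(np.zeros(1), np.eye(1)),
                         noise_prior=InverseGammaPrior(3, 1),
                         group_var_prior=InverseGammaPrior(3, 1))
        beta = rng.normal(size=1)
        s2y, s2e = 0.8, 0.4
        draws = 200_000
        etas = rng.normal(scale=np.sqrt(s2e), size=(draws, design.J))
        lls = np.array([
            loglik_full(design, spec, beta, VariancePoint(s2y, s2e),
                        LatentEffects(e[:, None]), include_group_density=False)
            for e in etas[:2000]])
        mx = lls.max()
        mc = mx + np.log(np.mean(np.exp(lls - mx)))
        se = np.std(np.exp(lls - mx), ddof=1) / (
            np.mean(np.exp(lls - mx)) * np.sqrt(lls.size))
        # oracle: dense marginal over eta only (beta fixed -> mean X beta)
        from scipy.stats import multivariate_normal
        same = design.group[:, None] == design.group[None, :]
        cov = s2y * np.eye(design.n) + s2e * same
        exact = multivariate_normal.logpdf(design.y, design.X @ beta, cov)
        assert abs(mc - exact) < 3 * max(se, 1e-3)
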