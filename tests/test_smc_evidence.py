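import numpy as np
import pytest
from scipy.stats import invgamma, norm

from oracles import quad_over_sigma2, random_grouped_design

from mlevidence.integrated_likelihood import (
    compute_sufficient_stats,
    log_evidence_nig,
)
from mlevidence.model_spec import (
    GaussianPrior,
    GroupedDesign,
    InverseGammaPrior,
    ModelSpec,
    NIGPrior,
)
from mlevidence.smc_evidence import (
    Correlation,
    EvidenceEstimate,
    IndependentSpace,
    LogVariance,
    SMCConfig,
    bayes_factor,
    estimate_evidence,
    interpret_log_bf,
    run_smc,
)
from mlevidence.model_spec import TruncatedNormalSpec


def nig_toy(seed=1, n=200, d=5):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, d - 1))])
    y = X @ rng.normal(size=d) + rng.normal(scale=0.5, size=n)
    design = GroupedDesign(y=y, X=X)
    nig = NIGPrior(3.0, 0.4, np.zeros(d), np.eye(d), gamma=5.0)
    return design, ModelSpec(kind="linear_nig", coef_prior=nig, name="nig")


class TestRunSMC:
    def test_constant_likelihood_gives_exact_zero_in_one_stage(self):
        space = IndependentSpace([LogVariance(InverseGammaPrior(3, 1), "s")])
        trace = run_smc(space.log_prior, lambda th: np.zeros(th.shape[0]),
                        space, SMCConfig(n_particles=200, seed=0),
                        np.random.default_rng(0))
        assert trace.log_evidence == 0.0
        assert trace.n_stages == 1
        assert trace.phis == [0.0, 1.0]

    def test_one_dimensional_quadrature_oracle(self):
        # evidence of 10 fixed observations under N(0, sigma2), IG(3,1) prior
        y = np.array([0.3, -1.2, 0.8, 0.1, -0.4, 1.5, -0.9, 0.2, 0.6, -0.2])
        prior = InverseGammaPrior(3.0, 1.0)

        def loglik_of_theta(th):
            s2 = np.exp(th[:, 0])
            return np.sum(norm.logpdf(y[None, :], scale=np.sqrt(s2)[:, None]),
                          axis=1)

        exact = quad_over_sigma2(
            lambda s2: float(np.sum(norm.logpdf(y, scale=np.sqrt(s2)))
                             + invgamma.logpdf(s2, 3, scale=1.0)))
        space = IndependentSpace([LogVariance(prior, "sigma2")])
        vals = []
        for seed in range(8):
            trace = run_smc(space.log_prior, loglik_of_theta, space,
                            SMCConfig(n_particles=500, seed=seed),
                            np.random.default_rng(seed))
            vals.append(trace.log_evidence)
        vals = np.array(vals)
        assert abs(vals.mean() - exact) < 3 * vals.std(ddof=1)

    def test_tempering_exponents_strictly_increase_to_one(self):
        design, spec = nig_toy()
        est = estimate_evidence(design, spec,
                                SMCConfig(n_particles=300, n_runs=2, seed=9))
        for trace in est.traces:
            phis = np.array(trace.phis)
            assert np.all(np.diff(phis) > 0)
            assert phis[0] == 0.0 and phis[-1] == 1.0

    def test_all_invalid_particles_raise(self):
        space = IndependentSpace([LogVariance(InverseGammaPrior(3, 1), "s")])
        with pytest.raises(RuntimeError, match="zero likelihood"):
            run_smc(space.log_prior,
                    lambda th: np.full(th.shape[0], -np.inf), space,
                    SMCConfig(n_particles=50, seed=0),
                    np.random.default_rng(0))


class TestEstimateEvidence:
    def test_same_seed_bit_identical(self):
        design, spec = nig_toy()
        cfg = SMCConfig(n_particles=300, n_runs=3, seed=42)
        a = estimate_evidence(design, spec, cfg)
        b = estimate_evidence(design, spec, cfg)
        assert a.per_run == b.per_run

    def test_matches_analytic_nig_evidence(self):
        design, spec = nig_toy()
        stats = compute_sufficient_stats(design)
        analytic = log_evidence_nig(stats, spec.coef_prior)
        est = estimate_evidence(design, spec,
                                SMCConfig(n_particles=800, n_runs=8, seed=7))
        assert abs(est.log_evidence_mean - analytic) < 3 * est.log_evidence_sd

    def test_full_mode_shares_engine_and_brackets_analytic(self):
        design, spec = nig_toy(n=100, d=3)
        stats = compute_sufficient_stats(design)
        analytic = log_evidence_nig(stats, spec.coef_prior)
        est = estimate_evidence(
            design, spec,
            SMCConfig(n_particles=1000, n_runs=6, seed=11, mode="full"))
        assert abs(est.log_evidence_mean - analytic) < 4 * est.log_evidence_sd

    def test_integrated_space_dimension_small(self, rng):
        # the point of marginalisation: only variances are sampled
        design = random_grouped_design(rng, n=30, d=4, J=3)
        spec = ModelSpec(kind="multilevel_intercept",
                         coef_prior=GaussianPrior(np.zeros(4), np.eye(4)),
                         noise_prior=InverseGammaPrior(3, 1),
                         group_var_prior=InverseGammaPrior(3, 1))
        est = estimate_evidence(design, spec,
                                SMCConfig(n_particles=100, n_runs=1, seed=0))
        assert est.traces[0].particles.shape[1] == 2
        assert est.traces[0].param_names == ("sigma2_y", "sigma2_eta")


class TestBayesFactor:
    def mk(self, value):
        return EvidenceEstimate(log_evidence_mean=value, log_evidence_sd=0.0,
                                per_run=[value], mode="integrated")

    def test_identical_estimates_no_evidence(self):
        log_bf, label = bayes_factor(self.mk(-10.0), self.mk(-10.0))
        assert log_bf == 0.0
        assert label == "no evidence either way"

    def test_antisymmetry(self):
        a, b = self.mk(-5.0), self.mk(-9.5)
        assert bayes_factor(a, b)[0] == -bayes_factor(b, a)[0]

    def test_printed_table_difference(self):
        # difference of two printed log evidences is the log Bayes factor
        log_bf, label = bayes_factor(self.mk(-681.06), self.mk(-753.53))
        assert log_bf == pytest.approx(72.47)
        assert "very strong" in label

    def test_band_edges(self):
        assert "bare mention" in interpret_log_bf(np.log(2.0))
        assert "positive" in interpret_log_bf(np.log(10.0))
        assert "strong" in interpret_log_bf(np.log(50.0))
        assert "favours second" in interpret_log_bf(-np.log(10.0))


class TestSamplerSpaces:
    def test_log_variance_prior_includes_jacobian(self):
        comp = LogVariance(InverseGammaPrior(3.0, 1.0), "s")
        x = np.array([[0.3]])
        expected = invgamma.logpdf(np.exp(0.3), 3, scale=1.0) + 0.3
        assert comp.log_prior(x)[0] == pytest.approx(expected)

    def test_correlation_out_of_range_has_zero_prior(self):
        comp = Correlation(TruncatedNormalSpec())
        assert comp.log_prior(np.array([[1.2]]))[0] == -np.inf
        assert np.isfinite(comp.log_prior(np.array([[0.5]]))[0])
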