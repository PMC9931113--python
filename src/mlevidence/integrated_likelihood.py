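"""Closed-form integrated log likelihoods for Gaussian linear models.

For a linear model y_i = beta' x_i + eps_i with eps_i ~ N(0, sigma^2) and a
conjugate Gaussian prior beta ~ N(mu, Sigma), the coefficients can be
marginalised analytically, leaving a function of sigma^2 alone:

    log p(D | sigma^2) = -1/2 ( log|Stilde^-1| + log|Sigma| + n log(2 pi sigma^2)
                                + mu' Sigma^-1 mu + Syy / sigma^2
                                - mutilde' Stilde^-1 mutilde )

with Stilde^-1 = Sigma^-1 + Sxx / sigma^2 and
mutilde = Stilde (Sigma^-1 mu + Sxy / sigma^2).  The same marginalisation
extends to multilevel models, where the group deviations eta_j are
integrated out as well: the intercept-only case leaves (sigma_y^2,
sigma_eta^2) and the general case leaves (sigma_y^2, nu), with per-group
m x m corrections entering through the group cross-products.

Everything here is a pure function of :class:`SufficientStats` (data-only
products computed once), priors, and variance parameters.  All
log-determinants and quadratic forms go through Cholesky factorisations;
no matrix is ever explicitly inverted at the d x d level.  Invalid
variance points (non-positive variances, non-SPD group covariances)
return ``-inf`` rather than raising, so Monte Carlo samplers can treat
them as zero-probability states.

The batched ``*Evaluator`` classes evaluate the same likelihoods at many
variance points at once; they are the workhorses of the SMC engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import gammaln

from .model_spec import (
    CovarianceStructure,
    GaussianPrior,
    GroupedDesign,
    LatentEffects,
    ModelSpec,
    NIGPrior,
    batched_cov_from_param,
    cov_from_param,
)

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))
NEG_INF = float("-inf")


# --------------------------------------------------------------------------
# sufficient statistics
# --------------------------------------------------------------------------

@dataclass
class SufficientStats:
    """All data-only products and sums the integrated likelihoods consume.

    Computed once per dataset; every likelihood evaluation afterwards is a
    function of these arrays and the variance parameters only.
    """

    n: int
    d: int
    m: int
    J: int
    n_j: np.ndarray          # (J,)
    Sxx: np.ndarray          # (d, d)   sum_i x x'
    Sxy: np.ndarray          # (d,)     sum_i x y
    Syy: float               # scalar   sum_i y^2
    gx: np.ndarray           # (J, d)   per-group sum_i x
    gy: np.ndarray           # (J,)     per-group sum_i y
    Szz: np.ndarray | None   # (J, m, m) per-group sum_i z z'
    Szy: np.ndarray | None   # (J, m)    per-group sum_i z y
    Sxz: np.ndarray | None   # (J, d, m) per-group sum_i x z'


def compute_sufficient_stats(design: GroupedDesign) -> SufficientStats:
    """Precompute every product and sum of the data used by Eqs-style
    integrated likelihoods (no dependence on any model parameter)."""
    y, X, Z, g = design.y, design.X, design.Z, design.group
    J, d, m = design.J, design.d, design.m
    Sxx = X.T @ X
    Sxx = (Sxx + Sxx.T) / 2.0
    Sxy = X.T @ y
    Syy = float(y @ y)
    gx = np.zeros((J, d))
    np.add.at(gx, g, X)
    gy = np.bincount(g, weights=y, minlength=J)
    if Z is not None:
        Szz = np.zeros((J, m, m))
        np.add.at(Szz, g, Z[:, :, None] * Z[:, None, :])
        Szz = (Szz + np.transpose(Szz, (0, 2, 1))) / 2.0
        Szy = np.zeros((J, m))
        np.add.at(Szy, g, Z * y[:, None])
        Sxz = np.zeros((J, d, m))
        np.add.at(Sxz, g, X[:, :, None] * Z[:, None, :])
    else:
        Szz = Szy = Sxz = None
    return SufficientStats(
        n=design.n, d=d, m=m, J=J, n_j=design.group_sizes.astype(float),
        Sxx=Sxx, Sxy=Sxy, Syy=Syy, gx=gx, gy=gy, Szz=Szz, Szy=Szy, Sxz=Sxz)


# --------------------------------------------------------------------------
# conditional coefficient posteriors
# --------------------------------------------------------------------------

@dataclass
class ConditionalGaussian:
    """Coefficient posterior beta | variances, D as (mean, precision).

    Quadratic forms and determinants use the stored Cholesky factor of the
    precision; the covariance is never formed explicitly.
    """

    mean: np.ndarray
    precision: np.ndarray
    chol: np.ndarray = field(repr=False)
    log_det_precision: float = 0.0

    def mahalanobis(self, b: np.ndarray) -> float:
        """(b - mean)' precision (b - mean) via the Cholesky factor."""
        w = self.chol.T @ (np.asarray(b, float) - self.mean)
        return float(w @ w)

    def covariance(self) -> np.ndarray:
        """Dense posterior covariance (small-d summaries only)."""
        eye = np.eye(self.mean.shape[0])
        Linv = sla.solve_triangular(self.chol, eye, lower=True)
        return Linv.T @ Linv


def _chol_with_jitter(P: np.ndarray, what: str) -> np.ndarray:
    """Cholesky of a precision matrix, with one logged jitter retry."""
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        d = P.shape[0]
        eps = 1e-10 * np.trace(P) / d
        logger.warning("jittering near-singular %s precision by %.3e", what, eps)
        return np.linalg.cholesky(P + eps * np.eye(d))


def _conditional_from_parts(P: np.ndarray, h: np.ndarray, what: str) -> ConditionalGaussian:
    L = _chol_with_jitter(P, what)
    mean = sla.cho_solve((L, True), h)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return ConditionalGaussian(mean=mean, precision=P, chol=L,
                               log_det_precision=logdet)


def conditional_posterior_linear(
    stats: SufficientStats, prior: GaussianPrior, sigma2: float,
) -> ConditionalGaussian:
    """Posterior N(mutilde, Stilde) of beta given sigma^2 for the linear model."""
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    Lam0 = prior.precision()
    P = Lam0 + stats.Sxx / sigma2
    h = Lam0 @ prior.mu + stats.Sxy / sigma2
    return _conditional_from_parts(P, h, "linear")


def _intercept_parts(stats, prior, sigma2_y, sigma2_eta):
    """Precision and linear term for the intercept-multilevel posterior."""
    r = sigma2_eta / (sigma2_y + stats.n_j * sigma2_eta)     # (J,)
    Lam0 = prior.precision()
    P = Lam0 + (stats.Sxx - np.einsum("j,ja,jb->ab", r, stats.gx, stats.gx)) / sigma2_y
    h = Lam0 @ prior.mu + (stats.Sxy - (r * stats.gy) @ stats.gx) / sigma2_y
    return P, h, r


def conditional_posterior_ml_intercept(
    stats: SufficientStats, prior: GaussianPrior,
    sigma2_y: float, sigma2_eta: float,
) -> ConditionalGaussian:
    """Posterior of beta given (sigma_y^2, sigma_eta^2), intercept deviations
    integrated out.  Reduces to the linear case at sigma_eta^2 = 0."""
    if not sigma2_y > 0 or sigma2_eta < 0:
        raise ValueError("variances must be positive (sigma_eta^2 >= 0)")
    P, h, _ = _intercept_parts(stats, prior, sigma2_y, sigma2_eta)
    return _conditional_from_parts(P, h, "multilevel-intercept")


def _general_parts(stats, prior, Sig_eta, sigma2_y):
    """Per-group conditionals and the beta-posterior parts, general model.

    Returns (P, h, logdet_sum, t3, logdet_eta) where ``logdet_sum`` is
    sum_j log|Shat_eta_j^-1|, ``t3 = sum_j Szy_j' Shat_eta_j Szy_j`` and
    ``logdet_eta = log|Sigma_eta|``.
    """
    m = stats.m
    Le = np.linalg.cholesky(Sig_eta)
    logdet_eta = 2.0 * float(np.sum(np.log(np.diag(Le))))
    eyem = np.eye(m)
    Linv = sla.solve_triangular(Le, eyem, lower=True)
    Sig_eta_inv = Linv.T @ Linv
    Pj = Sig_eta_inv[None, :, :] + stats.Szz / sigma2_y      # (J, m, m)
    Lj = np.linalg.cholesky(Pj)
    logdet_sum = float(2.0 * np.sum(np.log(np.diagonal(Lj, axis1=1, axis2=2))))
    Ehat = np.linalg.solve(Pj, np.broadcast_to(eyem, Pj.shape).copy())  # Shat_eta_j
    T1 = np.einsum("jdm,jmn,jen->de", stats.Sxz, Ehat, stats.Sxz)
    t2 = np.einsum("jdm,jmn,jn->d", stats.Sxz, Ehat, stats.Szy)
    t3 = float(np.einsum("jm,jmn,jn->", stats.Szy, Ehat, stats.Szy))
    Lam0 = prior.precision()
    s4 = sigma2_y * sigma2_y
    P = Lam0 + stats.Sxx / sigma2_y - T1 / s4
    h = Lam0 @ prior.mu + stats.Sxy / sigma2_y - t2 / s4
    return P, h, logdet_sum, t3, logdet_eta


@dataclass
class PerGroupConditional:
    """Cholesky factors and log-determinants of the per-group eta-posterior
    precisions Shat_eta_j^-1(sigma_y^2, nu)."""

    chols: np.ndarray        # (J, m, m)
    log_dets: np.ndarray     # (J,)


def per_group_conditionals(
    stats: SufficientStats, structure: CovarianceStructure,
    sigma2_y: float, nu,
) -> PerGroupConditional:
    Sig_eta, ok = cov_from_param(structure, nu)
    if not ok or not sigma2_y > 0:
        raise ValueError("invalid (sigma_y^2, nu) point")
    Le = np.linalg.cholesky(Sig_eta)
    Linv = sla.solve_triangular(Le, np.eye(stats.m), lower=True)
    Pj = (Linv.T @ Linv)[None] + stats.Szz / sigma2_y
    Lj = np.linalg.cholesky(Pj)
    logdets = 2.0 * np.sum(np.log(np.diagonal(Lj, axis1=1, axis2=2)), axis=1)
    return PerGroupConditional(chols=Lj, log_dets=logdets)


def conditional_posterior_ml_general(
    stats: SufficientStats, prior: GaussianPrior,
    structure: CovarianceStructure, sigma2_y: float, nu,
) -> ConditionalGaussian:
    """Posterior of beta given (sigma_y^2, nu) with vector group effects
    integrated out.  Reduces to the intercept case at m=1, z = 1."""
    Sig_eta, ok = cov_from_param(structure, nu)
    if not ok or not sigma2_y > 0:
        raise ValueError("invalid (sigma_y^2, nu) point")
    P, h, *_ = _general_parts(stats, prior, Sig_eta, sigma2_y)
    return _conditional_from_parts(P, h, "multilevel-general")


# --------------------------------------------------------------------------
# integrated log likelihoods (scalar API)
# --------------------------------------------------------------------------

def loglik_integrated_linear(
    stats: SufficientStats, prior: GaussianPrior, sigma2: float,
) -> float:
    """Log integrated likelihood of the linear model with beta marginalised."""
    if not sigma2 > 0 or not np.isfinite(sigma2):
        return NEG_INF
    if stats.n == 0:
        return 0.0
    ev = LinearIntegratedEvaluator(stats, prior)
    return float(ev.loglik(np.array([sigma2]))[0])


def loglik_integrated_nig(
    stats: SufficientStats, prior: NIGPrior, sigma2: float,
) -> float:
    """Log integrated likelihood under the NIG prior: identical to the
    Gaussian-prior form with coefficient covariance gamma sigma^2 Sigma."""
    if not sigma2 > 0 or not np.isfinite(sigma2):
        return NEG_INF
    if stats.n == 0:
        return 0.0
    return loglik_integrated_linear(
        stats, prior.coefficient_prior(sigma2), sigma2)


def loglik_integrated_ml_intercept(
    stats: SufficientStats, prior: GaussianPrior,
    sigma2_y: float, sigma2_eta: float,
) -> float:
    """Log integrated likelihood of the intercept-only multilevel model,
    beta and all eta_j marginalised.  sigma_eta^2 = 0 is the linear limit."""
    if not sigma2_y > 0 or sigma2_eta < 0:
        return NEG_INF
    if stats.n == 0:
        return 0.0
    ev = InterceptIntegratedEvaluator(stats, prior)
    return float(ev.loglik(np.array([sigma2_y]), np.array([sigma2_eta]))[0])


def loglik_integrated_ml_general(
    stats: SufficientStats, prior: GaussianPrior,
    structure: CovarianceStructure, sigma2_y: float, nu,
) -> float:
    """Log integrated likelihood of the general multilevel model; invalid
    (sigma_y^2, nu) points return -inf."""
    if not sigma2_y > 0:
        return NEG_INF
    if stats.n == 0:
        return 0.0
    ev = GeneralIntegratedEvaluator(stats, prior, structure)
    return float(ev.loglik(np.array([sigma2_y]),
                           np.atleast_2d(np.asarray(nu, float)))[0])


# --------------------------------------------------------------------------
# NIG analytic evidence and posterior
# --------------------------------------------------------------------------

def _nig_update(stats: SufficientStats, prior: NIGPrior):
    """Posterior pieces (a', b', muhat, chol of Shat^-1) under the NIG prior."""
    Sigma0 = prior.gamma * prior.Sigma          # effective covariance template
    base = GaussianPrior(prior.mu, Sigma0)
    Lam0 = base.precision()
    P = Lam0 + stats.Sxx
    L = _chol_with_jitter(P, "nig")
    h = Lam0 @ prior.mu + stats.Sxy
    muhat = sla.cho_solve((L, True), h)
    b_new = prior.b + 0.5 * (stats.Syy + prior.mu @ (Lam0 @ prior.mu) - muhat @ h)
    a_new = prior.a + stats.n / 2.0
    return a_new, float(b_new), muhat, L, base


def log_evidence_nig(stats: SufficientStats, prior: NIGPrior) -> float:
    """Analytic log model evidence under the conjugate NIG prior.

    log p(D) = -1/2 ( log|Shat^-1| + log|Sigma| + n log 2 pi
                      - 2 a log b + (2a + n) log b' - 2 log G(n/2 + a)
                      + 2 log G(a) )

    where Sigma here is the effective template gamma * Sigma.  An empty
    dataset gives exactly 0.
    """
    if stats.n == 0:
        return 0.0
    a_new, b_new, _, L, base = _nig_update(stats, prior)
    if not b_new > 0:
        raise ValueError("non-positive posterior scale b'; data inconsistent")
    logdet_P = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (
        logdet_P + base.log_det + stats.n * LOG_2PI
        - 2.0 * prior.a * np.log(prior.b)
        + (2.0 * prior.a + stats.n) * np.log(b_new)
        - 2.0 * gammaln(a_new) + 2.0 * gammaln(prior.a))


def nig_posterior(stats: SufficientStats, prior: NIGPrior) -> NIGPrior:
    """Conjugate update: NIG(a, b, mu, gamma Sigma) -> NIG(n/2 + a, b', muhat,
    Shat).  Updating with an empty dataset is the identity."""
    if stats.n == 0:
        return prior
    a_new, b_new, muhat, L, _ = _nig_update(stats, prior)
    eye = np.eye(stats.d)
    Linv = sla.solve_triangular(L, eye, lower=True)
    Shat = Linv.T @ Linv
    return NIGPrior(a=a_new, b=b_new, mu=muhat, Sigma=(Shat + Shat.T) / 2.0,
                    gamma=1.0)


# --------------------------------------------------------------------------
# full (unintegrated) log likelihood
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePoint:
    """One point in variance-parameter space.

    ``sigma2_y`` is the observation noise variance (plain sigma^2 for
    single-level models); ``sigma2_eta`` the intercept-deviation variance;
    ``nu`` the covariance parameter vector of the general model.
    """

    sigma2_y: float
    sigma2_eta: float | None = None
    nu: tuple | None = None

    @property
    def sigma2(self) -> float:
        return self.sigma2_y


def loglik_full(
    design: GroupedDesign, spec: ModelSpec, beta: np.ndarray,
    variances: VariancePoint, eta: LatentEffects | None = None,
    include_group_density: bool = True,
) -> float:
    """Joint log density of the data (and group effects) at explicit
    parameter values: sum of Gaussian residual log densities plus, for
    multilevel models, the Gaussian log densities of the eta_j.

    Set ``include_group_density=False`` for the data term alone (the
    likelihood used when eta is treated as part of the sampled state).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.d,):
        raise ValueError("beta dimension mismatch")
    s2y = variances.sigma2_y
    if not s2y > 0:
        return NEG_INF
    resid = design.y - design.X @ beta
    if spec.kind in ("multilevel_intercept", "multilevel_general"):
        if eta is None:
            raise ValueError("multilevel models need latent effects eta")
        if eta.J != design.J:
            raise ValueError("eta row count must equal number of groups")
        if spec.kind == "multilevel_intercept":
            resid = resid - eta.eta[design.group, 0]
        else:
            if design.Z is None or eta.m != design.m:
                raise ValueError("eta/Z dimension mismatch")
            resid = resid - np.einsum("im,im->i", design.Z, eta.eta[design.group])
    ll = -0.5 * (design.n * (LOG_2PI + np.log(s2y)) + resid @ resid / s2y)
    if include_group_density and spec.kind == "multilevel_intercept":
        s2e = variances.sigma2_eta
        if not s2e > 0:
            return NEG_INF
        e = eta.eta[:, 0]
        ll += -0.5 * (design.J * (LOG_2PI + np.log(s2e)) + e @ e / s2e)
    elif include_group_density and spec.kind == "multilevel_general":
        Sig_eta, ok = cov_from_param(spec.structure, np.asarray(variances.nu))
        if not ok:
            return NEG_INF
        L = np.linalg.cholesky(Sig_eta)
        w = sla.solve_triangular(L, eta.eta.T, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll += -0.5 * (design.J * (design.m * LOG_2PI + logdet) + float(np.sum(w * w)))
    return float(ll)


# --------------------------------------------------------------------------
# batched evaluators (used by the SMC engine)
# --------------------------------------------------------------------------

class LinearIntegratedEvaluator:
    """Vectorised linear-model integrated likelihood over many sigma^2.

    A one-off generalised eigendecomposition of (Sxx, Sigma) reduces each
    evaluation to O(d): with L = chol(Sigma) and L' Sxx L = Q diag(lam) Q',
    log|Stilde^-1| + log|Sigma| = sum log(1 + lam_i / sigma^2) and the
    quadratic form of mutilde diagonalises in the same basis.
    """

    def __init__(self, stats: SufficientStats, prior: GaussianPrior):
        self.stats = stats
        self.prior = prior
        L = prior.chol
        A = L.T @ stats.Sxx @ L
        lam, Q = np.linalg.eigh((A + A.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        # g0 = Q' L^-1 mu (so that sum g0^2 = mu' Sigma^-1 mu), g1 = Q' L' Sxy
        self.g0 = Q.T @ sla.solve_triangular(L, prior.mu, lower=True)
        self.g1 = Q.T @ (L.T @ stats.Sxy)
        self.mu_quad = float(self.g0 @ self.g0)

    def loglik(self, sigma2: np.ndarray) -> np.ndarray:
        sigma2 = np.asarray(sigma2, dtype=float)
        out = np.full(sigma2.shape, NEG_INF)
        ok = (sigma2 > 0) & np.isfinite(sigma2)
        if self.stats.n == 0:
            out[ok] = 0.0
            return out
        s2 = sigma2[ok][:, None]                       # (P, 1)
        denom = 1.0 + self.lam[None, :] / s2           # (P, d)
        h = self.g0[None, :] + self.g1[None, :] / s2
        quad = np.sum(h * h / denom, axis=1)
        out[ok] = -0.5 * (
            np.sum(np.log(denom), axis=1)
            + self.stats.n * (LOG_2PI + np.log(s2[:, 0]))
            + self.mu_quad + self.stats.Syy / s2[:, 0] - quad)
        return out


class NIGIntegratedEvaluator:
    """Vectorised NIG integrated likelihood over many sigma^2.

    Under beta | sigma^2 ~ N(mu, gamma sigma^2 Sigma) the sigma^2 factors
    collapse: with B = Sigma^-1 / gamma + Sxx fixed,

        log p(D | sigma^2) = -1/2 ( log|B| + log|gamma Sigma| + n log(2 pi sigma^2)
                                    + c / sigma^2 )

    where c = mu' Sigma^-1 mu / gamma + Syy - h0' B^-1 h0 and
    h0 = Sigma^-1 mu / gamma + Sxy.  Each evaluation is O(1).
    """

    def __init__(self, stats: SufficientStats, prior: NIGPrior):
        self.stats = stats
        base = GaussianPrior(prior.mu, prior.gamma * prior.Sigma)
        Lam0 = base.precision()
        B = Lam0 + stats.Sxx
        L = _chol_with_jitter(B, "nig")
        h0 = Lam0 @ prior.mu + stats.Sxy
        w = sla.cho_solve((L, True), h0)
        self.const = (2.0 * float(np.sum(np.log(np.diag(L)))) + base.log_det)
        self.c = float(prior.mu @ (Lam0 @ prior.mu) + stats.Syy - h0 @ w)

    def loglik(self, sigma2: np.ndarray) -> np.ndarray:
        sigma2 = np.asarray(sigma2, dtype=float)
        out = np.full(sigma2.shape, NEG_INF)
        ok = (sigma2 > 0) & np.isfinite(sigma2)
        if self.stats.n == 0:
            out[ok] = 0.0
            return out
        s2 = sigma2[ok]
        out[ok] = -0.5 * (self.const + self.stats.n * (LOG_2PI + np.log(s2))
                          + self.c / s2)
        return out


def _batched_gaussian_terms(P, h):
    """Batched Cholesky log-determinants and quadratic forms mutilde' h.

    P: (P, d, d) precisions, h: (P, d).  Points whose precision fails to
    factorise get -inf markers via the returned validity mask.
    """
    npts = P.shape[0]
    logdet = np.full(npts, np.nan)
    quad = np.full(npts, np.nan)
    valid = np.ones(npts, dtype=bool)
    try:
        L = np.linalg.cholesky(P)
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        mean = np.linalg.solve(P, h[:, :, None])[:, :, 0]
        quad = np.sum(mean * h, axis=1)
    except np.linalg.LinAlgError:
        for i in range(npts):
            try:
                Li = np.linalg.cholesky(P[i])
                logdet[i] = 2.0 * np.sum(np.log(np.diag(Li)))
                quad[i] = float(sla.cho_solve((Li, True), h[i]) @ h[i])
            except np.linalg.LinAlgError:
                valid[i] = False
    return logdet, quad, valid


class InterceptIntegratedEvaluator:
    """Vectorised intercept-multilevel integrated likelihood over many
    (sigma_y^2, sigma_eta^2) points."""

    def __init__(self, stats: SufficientStats, prior: GaussianPrior):
        self.stats = stats
        self.prior = prior
        self.Lam0 = prior.precision()
        self.h0 = self.Lam0 @ prior.mu
        self.mu_quad = float(prior.mu @ self.h0)
        self.GX = np.einsum("ja,jb->jab", stats.gx, stats.gx)

    def loglik(self, sigma2_y: np.ndarray, sigma2_eta: np.ndarray) -> np.ndarray:
        s2y = np.asarray(sigma2_y, dtype=float)
        s2e = np.asarray(sigma2_eta, dtype=float)
        out = np.full(s2y.shape, NEG_INF)
        ok = (s2y > 0) & (s2e >= 0) & np.isfinite(s2y) & np.isfinite(s2e)
        if self.stats.n == 0:
            out[ok] = 0.0
            return out
        if not np.any(ok):
            return out
        st = self.stats
        a, b = s2y[ok][:, None], s2e[ok][:, None]
        r = b / (a + st.n_j[None, :] * b)                       # (P, J)
        P = self.Lam0[None] + (st.Sxx[None] -
                               np.einsum("pj,jab->pab", r, self.GX)) / a[:, :, None]
        h = self.h0[None] + (st.Sxy[None] - (r * st.gy[None, :]) @ st.gx) / a
        logdet, quad, valid = _batched_gaussian_terms(P, h)
        log_ratio = np.sum(np.log1p(st.n_j[None, :] * b / a), axis=1)
        yterm = (st.Syy - np.sum(r * st.gy[None, :] ** 2, axis=1)) / a[:, 0]
        vals = -0.5 * (logdet + self.prior.log_det
                       + st.n * (LOG_2PI + np.log(a[:, 0]))
                       + log_ratio + self.mu_quad + yterm - quad)
        vals[~valid] = NEG_INF
        out[ok] = vals
        return out


class GeneralIntegratedEvaluator:
    """Vectorised general-multilevel integrated likelihood over many
    (sigma_y^2, nu) points; per-group m x m factorisations are recomputed
    at every point, as they must be."""

    def __init__(self, stats: SufficientStats, prior: GaussianPrior,
                 structure: CovarianceStructure):
        if stats.Szz is None:
            raise ValueError("general multilevel likelihood needs Z statistics")
        if structure.m != stats.m:
            raise ValueError("structure dimension does not match design")
        self.stats = stats
        self.prior = prior
        self.structure = structure
        self.Lam0 = prior.precision()
        self.h0 = self.Lam0 @ prior.mu
        self.mu_quad = float(prior.mu @ self.h0)

    def _covariances(self, nu: np.ndarray):
        return batched_cov_from_param(self.structure, nu)

    def loglik(self, sigma2_y: np.ndarray, nu: np.ndarray) -> np.ndarray:
        s2y = np.asarray(sigma2_y, dtype=float)
        nu = np.atleast_2d(np.asarray(nu, dtype=float))
        out = np.full(s2y.shape, NEG_INF)
        ok = (s2y > 0) & np.isfinite(s2y) & np.all(np.isfinite(nu), axis=1)
        if self.stats.n == 0:
            out[ok] = 0.0
            return out
        covs, cov_ok = self._covariances(nu)
        ok = ok & cov_ok
        if not np.any(ok):
            return out
        st = self.stats
        m, J = st.m, st.J
        a = s2y[ok]                                             # (P,)
        C = covs[ok]                                            # (P, m, m)
        try:
            Lc = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            # fall back: mark failing points invalid one by one
            sub_ok = np.ones(C.shape[0], dtype=bool)
            for i in range(C.shape[0]):
                try:
                    np.linalg.cholesky(C[i])
                except np.linalg.LinAlgError:
                    sub_ok[i] = False
            idx = np.flatnonzero(ok)
            ok[idx[~sub_ok]] = False
            if not np.any(ok):
                return out
            a, C = s2y[ok], covs[ok]
            Lc = np.linalg.cholesky(C)
        logdet_eta = 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)), axis=1)
        eye = np.eye(m)
        C_inv = np.linalg.solve(C, np.broadcast_to(eye, C.shape).copy())
        # per-group posterior precisions of eta_j: (P, J, m, m)
        Pj = C_inv[:, None, :, :] + st.Szz[None, :, :, :] / a[:, None, None, None]
        Lj = np.linalg.cholesky(Pj)
        logdet_sum = 2.0 * np.sum(
            np.log(np.diagonal(Lj, axis1=2, axis2=3)), axis=(1, 2))
        Ehat = np.linalg.solve(
            Pj, np.broadcast_to(eye, Pj.shape).copy())          # Shat_eta_j
        T1 = np.einsum("jdm,pjmn,jen->pde", st.Sxz, Ehat, st.Sxz)
        t2 = np.einsum("jdm,pjmn,jn->pd", st.Sxz, Ehat, st.Szy)
        t3 = np.einsum("jm,pjmn,jn->p", st.Szy, Ehat, st.Szy)
        s4 = (a * a)[:, None]
        P = self.Lam0[None] + st.Sxx[None] / a[:, None, None] - T1 / s4[:, :, None]
        h = self.h0[None] + st.Sxy[None] / a[:, None] - t2 / s4
        logdet, quad, valid = _batched_gaussian_terms(P, h)
        vals = -0.5 * (logdet + self.prior.log_det
                       + st.n * (LOG_2PI + np.log(a))
                       + J * logdet_eta + logdet_sum
                       + self.mu_quad + st.Syy / a - t3 / (a * a) - quad)
        vals[~valid] = NEG_INF
        out[ok] = vals
        return out
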