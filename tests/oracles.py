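"""Independent oracles used by the test suite.

Everything here recomputes quantities through routes the library does not
use: dense marginal Gaussian densities, adaptive quadrature over
coefficients or variances, and plain Monte Carlo marginalisation.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal


def dense_marginal_loglik(design, mu, Sigma, s2y, s2e=None, Sig_eta=None):
    """log N(y; X mu, s2y I + [group blocks] + X Sigma X') computed densely.

    The group term is s2e * 1{same group} for the intercept model, or
    z_i' Sig_eta z_k * 1{same group} for the general model.
    """
    n = design.n
    cov = s2y * np.eye(n) + design.X @ Sigma @ design.X.T
    same = design.group[:, None] == design.group[None, :]
    if s2e is not None:
        cov = cov + s2e * same
    if Sig_eta is not None:
        cov = cov + (design.Z @ Sig_eta @ design.Z.T) * same
    return float(multivariate_normal.logpdf(design.y, design.X @ mu, cov))


def quad_loglik_beta(design, mu, Sigma, sigma2, shift):
    """log of the d<=2 coefficient integral by adaptive quadrature.

    Integrates exp(log N(y | X beta, sigma2 I) + log N(beta | mu, Sigma)
    - shift) over beta and returns log(integral) + shift.  Bounds cover
    +-12 prior standard deviations around the prior mean.
    """
    d = mu.shape[0]
    sd = np.sqrt(np.diag(Sigma))
    Sinv = np.linalg.inv(Sigma)
    _, logdet = np.linalg.slogdet(Sigma)
    X, y, n = design.X, design.y, design.n

    def logint(beta):
        beta = np.asarray(beta)
        r = y - X @ beta
        db = beta - mu
        return (-0.5 * (n * np.log(2 * np.pi * sigma2) + r @ r / sigma2)
                - 0.5 * (d * np.log(2 * np.pi) + logdet + db @ Sinv @ db))

    if d == 1:
        f = lambda b: np.exp(logint(np.array([b])) - shift)
        val, _ = integrate.quad(f, mu[0] - 12 * sd[0], mu[0] + 12 * sd[0],
                                limit=200)
    elif d == 2:
        f = lambda b1, b0: np.exp(logint(np.array([b0, b1])) - shift)
        val, _ = integrate.dblquad(
            f, mu[0] - 12 * sd[0], mu[0] + 12 * sd[0],
            lambda _: mu[1] - 12 * sd[1], lambda _: mu[1] + 12 * sd[1])
    else:
        raise ValueError("quadrature oracle handles d <= 2 only")
    return float(np.log(val) + shift)


def quad_over_sigma2(logpost, bracket=(-10.0, 6.0)):
    """log integral of exp(logpost(sigma2)) d sigma2 by quadrature in
    log-variance space, centred on the mode so narrow peaks are not missed.

    ``logpost`` maps sigma2 > 0 to a log density contribution.
    """
    g = lambda ls: logpost(np.exp(ls)) + ls          # includes the Jacobian
    r = minimize_scalar(lambda ls: -g(ls), bounds=bracket, method="bounded",
                        options={"xatol": 1e-10})
    mode, shift = r.x, -r.fun
    f = lambda ls: np.exp(g(ls) - shift)
    val, _ = integrate.quad(f, mode - 16, mode + 16, limit=400)
    return float(np.log(val) + shift)


def mc_marginal_loglik(design, mu, Sigma, s2y, rng, n_draws=1_000_000,
                       s2e=None, Sig_eta=None):
    """Monte-Carlo marginalisation over (beta, eta) by prior sampling.

    Returns (log mean likelihood, delta-method standard error of the log).
    """
    L = np.linalg.cholesky(Sigma)
    beta = mu[None, :] + rng.standard_normal((n_draws, mu.shape[0])) @ L.T
    resid = design.y[None, :] - beta @ design.X.T
    J = design.J
    if s2e is not None:
        eta = rng.normal(scale=np.sqrt(s2e), size=(n_draws, J))
        resid = resid - eta[:, design.group]
    elif Sig_eta is not None:
        m = Sig_eta.shape[0]
        Le = np.linalg.cholesky(Sig_eta)
        eta = rng.standard_normal((n_draws, J, m)) @ Le.T
        resid = resid - np.einsum("pim,im->pi", eta[:, design.group, :], design.Z)
    ll = -0.5 * (design.n * np.log(2 * np.pi * s2y)
                 + np.sum(resid * resid, axis=1) / s2y)
    mx = ll.max()
    w = np.exp(ll - mx)
    mean = w.mean()
    se_log = w.std(ddof=1) / (mean * np.sqrt(n_draws))
    return float(mx + np.log(mean)), float(se_log)


def random_grouped_design(rng, n=8, d=2, J=3, m=0, with_z=None):
    """A small random grouped design with every group occupied."""
    from mlevidence.model_spec import GroupedDesign

    base = np.arange(J)
    extra = rng.integers(0, J, size=n - J)
    g = np.sort(np.concatenate([base, extra]))
    X = rng.normal(size=(n, d))
    X[:, 0] = 1.0
    Z = rng.normal(size=(n, m)) if m else None
    if Z is not None:
        Z[:, 0] = 1.0
    y = rng.normal(size=n)
    return GroupedDesign(y=y, X=X, Z=Z, group=g)


def random_spd(rng, d, scale=1.0):
    A = rng.normal(size=(d, d))
    return scale * (A @ A.T + d * np.eye(d))
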