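"""Coefficient posteriors recovered from variance traces, and Mahalanobis
recovery diagnostics.

After integrated-likelihood sampling, the posterior over coefficients is a
mixture of Gaussians: for each sampled variance point the conditional
posterior N(mutilde, Stilde) is available in closed form, so the
coefficient posterior is recovered by averaging those conditionals over
the variance trace.  The recovery of a known coefficient vector ``b`` is
scored by a Mahalanobis distance in two forms:

integrated trace
    d = (1/N) sum_n (b - mutilde(v_n))' Stilde^-1(v_n) (b - mutilde(v_n)),
    the average of per-draw quadratic forms (the canonical form here).

full trace
    d = (b - beta_bar)' V^-1 (b - beta_bar) with the sample mean and
    sample covariance (1/(N-1) normaliser) of explicit beta draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrated_likelihood import (
    ConditionalGaussian,
    SufficientStats,
    conditional_posterior_linear,
    conditional_posterior_ml_general,
    conditional_posterior_ml_intercept,
)
from .model_spec import ModelSpec
from .smc_evidence import VarianceTrace

__all__ = [
    "CoefficientPosterior",
    "conditional_for",
    "mahalanobis_integrated",
    "mahalanobis_full",
    "pooled_beta_posterior",
    "beta_draws_from_trace",
]


def conditional_for(
    spec: ModelSpec, stats: SufficientStats, point: np.ndarray,
) -> ConditionalGaussian:
    """Conditional coefficient posterior at one natural-scale variance point
    (ordered as in the integrated-mode trace for this model kind)."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    if spec.kind == "linear":
        return conditional_posterior_linear(stats, spec.coef_prior, point[0])
    if spec.kind == "linear_nig":
        return conditional_posterior_linear(
            stats, spec.coef_prior.coefficient_prior(point[0]), point[0])
    if spec.kind == "multilevel_intercept":
        return conditional_posterior_ml_intercept(
            stats, spec.coef_prior, point[0], point[1])
    if spec.kind == "multilevel_general":
        return conditional_posterior_ml_general(
            stats, spec.coef_prior, spec.structure, point[0], point[1:])
    raise ValueError(f"unsupported model kind {spec.kind!r}")


def _variance_points(trace: VarianceTrace, spec: ModelSpec) -> np.ndarray:
    """Variance columns of a trace (drops beta/eta columns of full-mode runs)."""
    pts = trace.particles
    names = trace.param_names
    keep = [i for i, nm in enumerate(names)
            if not (nm.startswith("beta_") or nm.startswith("eta_"))]
    pts = pts[:, keep]
    if pts.shape[0] == 0:
        raise ValueError("empty variance trace")
    return pts


def mahalanobis_integrated(
    b: np.ndarray, trace: VarianceTrace, stats: SufficientStats,
    spec: ModelSpec, max_draws: int | None = None,
) -> float:
    """Average per-draw quadratic form between ``b`` and the conditional
    coefficient posteriors along a variance trace.

    This is the integrated-trace distance: each draw contributes
    (b - mutilde)' Stilde^-1 (b - mutilde) at its own variance point, and
    the draws are averaged -- not pooled into a single covariance first.
    ``max_draws`` optionally thins the trace to its first so-many unique
    points for speed.
    """
    b = np.asarray(b, dtype=float)
    pts = _variance_points(trace, spec)
    uniq = np.unique(pts, axis=0)
    if max_draws is not None and uniq.shape[0] > max_draws:
        uniq = uniq[:: max(1, uniq.shape[0] // max_draws)][:max_draws]
        pts = uniq
        counts = np.ones(len(uniq))
    else:
        # particle clouds repeat points after resampling; weight by count
        uniq, counts = np.unique(pts, axis=0, return_counts=True)
        pts = uniq
    total = 0.0
    for point, c in zip(pts, counts):
        total += c * conditional_for(spec, stats, point).mahalanobis(b)
    return float(total / counts.sum())


def mahalanobis_full(b: np.ndarray, coefficient_draws: np.ndarray) -> float:
    """Mahalanobis distance of ``b`` from the empirical distribution of
    explicit coefficient draws: (b - beta_bar)' V^-1 (b - beta_bar) with the
    unbiased (1/(N-1)) sample covariance V."""
    draws = np.atleast_2d(np.asarray(coefficient_draws, dtype=float))
    n, d = draws.shape
    if n < d + 1:
        raise ValueError(
            f"need at least d+1={d+1} draws for an invertible sample "
            f"covariance, got {n}")
    bbar = draws.mean(axis=0)
    centred = draws - bbar
    V = centred.T @ centred / (n - 1)
    diff = np.asarray(b, dtype=float) - bbar
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        rank = np.linalg.matrix_rank(V)
        raise ValueError(
            f"singular sample covariance (rank {rank} < {d}); "
            "draws may be degenerate") from exc
    w = np.linalg.solve(L, diff)
    return float(w @ w)


def beta_draws_from_trace(trace: VarianceTrace) -> np.ndarray:
    """Extract the explicit coefficient draws from a full-mode trace."""
    idx = [i for i, nm in enumerate(trace.param_names) if nm.startswith("beta_")]
    if not idx:
        raise ValueError("trace has no beta columns (integrated mode?)")
    return trace.particles[:, idx]


@dataclass
class CoefficientPosterior:
    """Pooled coefficient posterior from an integrated-mode variance trace.

    ``covariance_within`` is the plain average of the conditional
    covariances Stilde over the trace; ``covariance_total`` adds the
    spread of the conditional means between draws (law of total variance).
    ``variant`` records which of the two ``covariance`` holds.
    """

    mean: np.ndarray
    covariance: np.ndarray
    covariance_within: np.ndarray
    covariance_total: np.ndarray
    variant: str
    n_draws: int


def pooled_beta_posterior(
    trace: VarianceTrace, stats: SufficientStats, spec: ModelSpec,
    variant: str = "within",
) -> CoefficientPosterior:
    """Average the conditional coefficient posteriors over a variance trace.

    variant="within" returns the plain average of conditional covariances;
    variant="total" adds the between-draw covariance of the conditional
    means.  Both are always computed and recorded.
    """
    if variant not in ("within", "total"):
        raise ValueError("variant must be 'within' or 'total'")
    pts = _variance_points(trace, spec)
    uniq, counts = np.unique(pts, axis=0, return_counts=True)
    w = counts / counts.sum()
    d = stats.d
    mean = np.zeros(d)
    within = np.zeros((d, d))
    second = np.zeros((d, d))
    for point, wi in zip(uniq, w):
        cond = conditional_for(spec, stats, point)
        mean += wi * cond.mean
        within += wi * cond.covariance()
        second += wi * np.outer(cond.mean, cond.mean)
    between = second - np.outer(mean, mean)
    total = within + between
    return CoefficientPosterior(
        mean=mean,
        covariance=within if variant == "within" else total,
        covariance_within=within, covariance_total=total,
        variant=variant, n_draws=int(counts.sum()))
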