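"""Domain types for grouped regression data, priors, and model definitions.

The central container is :class:`GroupedDesign`, which holds an outcome
vector ``y``, an individual-level design matrix ``X`` and, for models in
which coefficients vary by group, a group-varying design matrix ``Z``
together with a dense group index.  Models are described by
:class:`ModelSpec`, which pairs a design with coefficient and variance
priors.  Four model kinds are supported:

``linear``
    y_i = beta' x_i + eps_i with beta ~ N(mu, Sigma) and a free noise
    variance sigma^2.
``linear_nig``
    The same likelihood under a joint normal-inverse-gamma prior
    beta | sigma^2 ~ N(mu, gamma sigma^2 Sigma), sigma^2 ~ IG(a, b),
    for which the model evidence is available in closed form.
``multilevel_intercept``
    y_ij = beta' x_ij + eta_j + eps_ij with scalar group deviations
    eta_j ~ N(0, sigma_eta^2) (partial pooling of intercepts).
``multilevel_general``
    y_ij = beta' x_ij + eta_j' z_ij + eps_ij with vector group effects
    eta_j ~ N(0, Sigma_eta(nu)), where the covariance Sigma_eta is
    parameterised through a vector nu (see :class:`CovarianceStructure`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla


__all__ = [
    "GroupedDesign",
    "GaussianPrior",
    "InverseGammaPrior",
    "NIGPrior",
    "TruncatedNormalSpec",
    "CovarianceStructure",
    "ModelSpec",
    "LatentEffects",
    "build_design",
    "cov_from_param",
]


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class GroupedDesign:
    """Outcome, design matrices and group membership for one dataset.

    Attributes
    ----------
    y : (n,) outcome vector.
    X : (n, d) individual-level design matrix.
    Z : (n, m) group-varying design matrix, or ``None`` for single-level
        and intercept-only multilevel models.
    group : (n,) integer array of dense 0-based group indices in
        first-appearance order.  ``group_labels[j]`` gives the original
        label of group ``j``.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None = None
    group: np.ndarray | None = None
    group_labels: Sequence = ()

    def __post_init__(self) -> None:
        self.y = _as_float_array(self.y, "y", 1)
        self.X = _as_float_array(self.X, "X", 2)
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X and y have inconsistent row counts")
        if self.group is None:
            self.group = np.zeros(n, dtype=np.intp)
        else:
            self.group = np.asarray(self.group, dtype=np.intp)
            if self.group.shape != (n,):
                raise ValueError("group index must have one entry per row")
        J = int(self.group.max()) + 1 if n else 0
        counts = np.bincount(self.group, minlength=J)
        if n and np.any(counts == 0):
            raise ValueError("group indices must be dense: every group needs >=1 row")
        self.group_sizes = counts
        if self.Z is not None:
            self.Z = _as_float_array(self.Z, "Z", 2)
            if self.Z.shape[0] != n:
                raise ValueError("Z and y have inconsistent row counts")
        if not self.group_labels:
            self.group_labels = list(range(1, J + 1))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    @property
    def J(self) -> int:
        return len(self.group_sizes)

    def permuted(self, order: np.ndarray) -> "GroupedDesign":
        """Return the design with rows reordered (group labels preserved)."""
        labels = np.asarray(self.group_labels, dtype=object)[self.group][order]
        return build_design_from_arrays(
            self.y[order], self.X[order],
            None if self.Z is None else self.Z[order], labels)


def build_design_from_arrays(y, X, Z, group_labels) -> GroupedDesign:
    """Assemble a :class:`GroupedDesign`, densifying group labels.

    Labels are mapped to 0-based indices in order of first appearance.
    """
    labels = np.asarray(group_labels)
    uniq, idx = np.unique(labels, return_index=True)
    order = np.argsort(idx)
    first_appearance = uniq[order]
    lookup = {lab: j for j, lab in enumerate(first_appearance)}
    group = np.array([lookup[lab] for lab in labels], dtype=np.intp)
    return GroupedDesign(y=y, X=X, Z=Z, group=group,
                         group_labels=list(first_appearance))


def build_design(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    group: str | None = None,
    z_covariates: Sequence[str] = (),
) -> GroupedDesign:
    """Build a :class:`GroupedDesign` from a labelled table.

    Parameters
    ----------
    table : data frame with one row per observation.
    outcome : name of the outcome column.
    covariates : names of the individual-level design columns (X).
    group : optional name of the group-label column.
    z_covariates : names of the group-varying design columns (Z).

    Raises
    ------
    ValueError on a missing column, an empty table, or missing values.
    """
    if len(table) == 0:
        raise ValueError("empty table: no observations to build a design from")
    needed = [outcome, *covariates, *z_covariates]
    if group is not None:
        needed.append(group)
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required column(s): {missing}")
    numeric = [outcome, *covariates, *z_covariates]
    sub = table[numeric]
    if sub.isna().to_numpy().any():
        bad = [c for c in numeric if table[c].isna().any()]
        raise ValueError(f"missing values in column(s): {bad}")
    y = sub[outcome].to_numpy(dtype=float)
    X = sub[list(covariates)].to_numpy(dtype=float)
    Z = sub[list(z_covariates)].to_numpy(dtype=float) if z_covariates else None
    labels = table[group].to_numpy() if group is not None else np.zeros(len(table))
    return build_design_from_arrays(y, X, Z, labels)


@dataclass
class GaussianPrior:
    """Multivariate normal prior N(mu, Sigma) for regression coefficients."""

    mu: np.ndarray
    Sigma: np.ndarray
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        d = self.mu.shape[0]
        if self.Sigma.shape != (d, d):
            raise ValueError("Sigma shape does not match mu")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive-definite") from exc

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    @property
    def chol(self) -> np.ndarray:
        return self._chol

    @property
    def log_det(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    def precision(self) -> np.ndarray:
        eye = np.eye(self.d)
        Linv = sla.solve_triangular(self._chol, eye, lower=True)
        return Linv.T @ Linv

    def scaled(self, factor: float) -> "GaussianPrior":
        return GaussianPrior(self.mu, factor * self.Sigma)


@dataclass(frozen=True)
class InverseGammaPrior:
    """IG(a, b) prior for a variance component; mean is b / (a - 1)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("inverse-gamma hyperparameters must be positive")

    @property
    def mean(self) -> float:
        if self.a <= 1:
            return float("inf")
        return self.b / (self.a - 1.0)


@dataclass
class NIGPrior:
    """Normal-inverse-gamma prior NIG(a, b, mu, gamma * Sigma).

    Conditionally, beta | sigma^2 ~ N(mu, gamma sigma^2 Sigma) and
    sigma^2 ~ IG(a, b).  ``Sigma`` is a covariance template; ``gamma`` is a
    scalar multiplier on it (gamma = 1 / E[sigma^2] makes the marginal
    coefficient covariance approximately Sigma).
    """

    a: float
    b: float
    mu: np.ndarray
    Sigma: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        base = GaussianPrior(self.mu, self.Sigma)
        self.mu = base.mu
        self.Sigma = base.Sigma

    @property
    def d(self) -> int:
        return self.mu.shape[0]

    def coefficient_prior(self, sigma2: float = 1.0) -> GaussianPrior:
        """Conditional Gaussian prior for beta at a given sigma^2."""
        return GaussianPrior(self.mu, self.gamma * sigma2 * self.Sigma)


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Normal(mean, sd^2) truncated to [lower, upper]."""

    mean: float = 0.0
    sd: float = 1.0
    lower: float = -1.0
    upper: float = 1.0


@dataclass
class CovarianceStructure:
    """Parameterisation nu -> Sigma_eta(nu) of a group-effect covariance.

    kinds
    -----
    ``diagonal``
        nu = (s_1^2, ..., s_m^2), Sigma_eta = diag(nu).
    ``pair_correlation``
        m = 2, nu = (s_1^2, s_2^2, rho); off-diagonal rho * s_1 * s_2
        (unless ``fixed_rho`` is set, in which case nu = (s_1^2, s_2^2)).
    ``banded_shared_rho``
        nu = (s_1^2, ..., s_m^2[, rho]); diagonal s_i^2 and adjacent-pair
        off-diagonals rho * s_i * s_{i+1} with a single shared rho.
        With ``fixed_rho`` set, rho is not part of nu.
    ``full_cholesky``
        nu packs a lower-triangular Cholesky factor L of Sigma_eta
        column-major, with the diagonal stored on the log scale;
        Sigma_eta = L L'.  Always valid.

    Out-of-range correlations (|rho| > 1) or non-positive variances are
    *flagged*, not repaired: :func:`cov_from_param` returns ``valid=False``
    and samplers treat the point as having zero probability.
    """

    kind: str
    m: int
    param_names: tuple[str, ...] = ()
    rho_prior: TruncatedNormalSpec | None = None
    fixed_rho: float | None = None

    def __post_init__(self) -> None:
        kinds = {"diagonal", "pair_correlation", "banded_shared_rho", "full_cholesky"}
        if self.kind not in kinds:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if self.kind == "pair_correlation" and self.m != 2:
            raise ValueError("pair_correlation requires m = 2")
        if not self.param_names:
            self.param_names = tuple(self._default_names())

    def _default_names(self) -> list[str]:
        if self.kind == "diagonal":
            return [f"sigma2_nu_{i+1}" for i in range(self.m)]
        if self.kind in ("pair_correlation", "banded_shared_rho"):
            names = [f"sigma2_nu_{i+1}" for i in range(self.m)]
            if self.fixed_rho is None:
                names.append("rho")
            return names
        n_tri = self.m * (self.m + 1) // 2
        return [f"chol_{i+1}" for i in range(n_tri)]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_variance_components(self) -> int:
        """Number of nu components that are variances (not correlations)."""
        if self.kind in ("diagonal", "pair_correlation", "banded_shared_rho"):
            return self.m
        return 0


def cov_from_param(structure: CovarianceStructure, nu) -> tuple[np.ndarray, bool]:
    """Map a parameter vector nu to (Sigma_eta, valid).

    Returns the m x m symmetric matrix and a flag that is ``False`` when
    the point is outside the valid region (|rho| > 1, non-positive
    variance, or a numerically non-positive-definite result).  The matrix
    is exactly symmetric by construction.
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    if nu.shape[0] != structure.n_params:
        raise ValueError(
            f"nu has length {nu.shape[0]}, expected {structure.n_params}")
    m = structure.m
    kind = structure.kind
    if kind == "diagonal":
        valid = bool(np.all(nu > 0))
        return np.diag(nu), valid
    if kind in ("pair_correlation", "banded_shared_rho"):
        if structure.fixed_rho is not None:
            var, rho = nu, structure.fixed_rho
        else:
            var, rho = nu[:-1], float(nu[-1])
        valid = bool(np.all(var > 0)) and abs(rho) <= 1.0
        if not valid:
            return np.diag(np.abs(var) + 1e-300), False
        s = np.sqrt(var)
        cov = np.diag(var)
        off = rho * s[:-1] * s[1:]
        idx = np.arange(m - 1)
        cov[idx, idx + 1] = off
        cov[idx + 1, idx] = off
        # shared adjacent-pair rho can still break positive-definiteness
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return cov, False
        return cov, True
    # full_cholesky: log-diagonal lower-triangular factor, always SPD
    L = np.zeros((m, m))
    rows, cols = np.tril_indices(m)
    L[rows, cols] = nu
    diag = np.arange(m)
    L[diag, diag] = np.exp(L[diag, diag])
    cov = L @ L.T
    return (cov + cov.T) / 2.0, True


def batched_cov_from_param(
    structure: CovarianceStructure, nu: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`cov_from_param` over rows of ``nu``.

    Returns (covs, valid) with shapes (P, m, m) and (P,).  The banded and
    pair-correlation kinds are built in closed form; other kinds fall back
    to the scalar map row by row.
    """
    nu = np.atleast_2d(np.asarray(nu, dtype=float))
    npts = nu.shape[0]
    m = structure.m
    if structure.kind in ("pair_correlation", "banded_shared_rho"):
        if structure.fixed_rho is not None:
            var = nu
            rho = np.full(npts, structure.fixed_rho)
        else:
            var, rho = nu[:, :-1], nu[:, -1]
        valid = np.all(var > 0, axis=1) & (np.abs(rho) <= 1.0)
        covs = np.zeros((npts, m, m))
        idx = np.arange(m)
        covs[:, idx, idx] = np.abs(var) + 1e-300
        s = np.sqrt(np.abs(var))
        off = rho[:, None] * s[:, :-1] * s[:, 1:]
        i = np.arange(m - 1)
        rows = np.flatnonzero(valid)
        covs[rows[:, None], i[None, :], i[None, :] + 1] = off[valid]
        covs[rows[:, None], i[None, :] + 1, i[None, :]] = off[valid]
        # positive-definiteness check on the candidates that remain
        cand = rows
        if cand.size:
            try:
                np.linalg.cholesky(covs[cand])
            except np.linalg.LinAlgError:
                for k in cand:
                    try:
                        np.linalg.cholesky(covs[k])
                    except np.linalg.LinAlgError:
                        valid[k] = False
                        covs[k] = np.diag(np.diag(covs[k]))
        return covs, valid
    covs = np.empty((npts, m, m))
    valid = np.ones(npts, dtype=bool)
    for k in range(npts):
        covs[k], valid[k] = cov_from_param(structure, nu[k])
    return covs, valid


@dataclass
class ModelSpec:
    """A model definition: kind, coefficient prior, and variance priors."""

    kind: str
    coef_prior: GaussianPrior | NIGPrior
    noise_prior: InverseGammaPrior | None = None
    group_var_prior: InverseGammaPrior | None = None
    structure: CovarianceStructure | None = None
    component_priors: tuple[InverseGammaPrior, ...] = ()
    name: str = ""
    x_columns: tuple[str, ...] = ()
    z_columns: tuple[str, ...] = ()

    KINDS = ("linear", "linear_nig", "multilevel_intercept", "multilevel_general")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "linear_nig":
            if not isinstance(self.coef_prior, NIGPrior):
                raise ValueError("linear_nig requires an NIGPrior")
        elif not isinstance(self.coef_prior, GaussianPrior):
            raise ValueError(f"{self.kind} requires a GaussianPrior on beta")
        if self.kind in ("linear", "multilevel_intercept", "multilevel_general"):
            if self.noise_prior is None:
                raise ValueError(f"{self.kind} requires a noise variance prior")
        if self.kind == "multilevel_intercept" and self.group_var_prior is None:
            raise ValueError("multilevel_intercept requires a group variance prior")
        if self.kind == "multilevel_general":
            if self.structure is None:
                raise ValueError("multilevel_general requires a CovarianceStructure")
            if len(self.component_priors) != self.structure.n_variance_components:
                raise ValueError(
                    "need one variance prior per covariance component "
                    f"({self.structure.n_variance_components}), "
                    f"got {len(self.component_priors)}")

    @property
    def is_multilevel(self) -> bool:
        return self.kind in ("multilevel_intercept", "multilevel_general")

    def validate_against(self, design: GroupedDesign) -> None:
        if self.coef_prior.d != design.d:
            raise ValueError(
                f"coefficient prior dimension {self.coef_prior.d} does not "
                f"match design d={design.d}")
        if self.kind == "multilevel_general":
            if design.Z is None:
                raise ValueError("multilevel_general requires a Z matrix")
            if self.structure.m != design.m:
                raise ValueError(
                    f"covariance structure m={self.structure.m} does not "
                    f"match design m={design.m}")
        if self.is_multilevel and design.J < 1:
            raise ValueError("multilevel models require group information")


@dataclass
class LatentEffects:
    """Group-level deviations eta, one row per group (m = 1: intercepts)."""

    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.atleast_2d(np.asarray(self.eta, dtype=float))

    @property
    def J(self) -> int:
        return self.eta.shape[0]

    @property
    def m(self) -> int:
        return self.eta.shape[1]
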