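"""Minnesota radon case study: loader, model builders M0-M5, AIC, table.

The dataset contains log radon measurements in houses (grouped by county),
an indicator for the floor the measurement was taken on (0 = basement,
1 = first floor), and a county-level uranium concentration.  Outcome and
uranium are standardised; the floor enters every design as the pair
(1 - t, t) so that basement and first-floor measurements carry the same
prior uncertainty.

The model ladder spans the pooling spectrum:

M0  complete pooling:            x = (1 - t, t)
M1  complete pooling + uranium:  x = (1 - t, t, v_county)
M2  unpooled intercepts:         x = (county indicators, 1 - t, t)
M3  no pooling:                  x = county-by-floor indicators
                                 (first-floor columns dropped for counties
                                 with no first-floor measurements)
M4  partial pooling:             x = (1 - t, t, v), intercept deviation eta_j
M5  varying slopes + intercepts: as M4 plus z = (1 - t, t) with a
                                 correlated 2 x 2 group covariance

All models put N(0, I) on the coefficients and IG(3, 1) on each univariate
variance; M5's correlation has a truncated-normal prior on [-1, 1].
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .integrated_likelihood import compute_sufficient_stats
from .model_spec import (
    CovarianceStructure,
    GaussianPrior,
    GroupedDesign,
    InverseGammaPrior,
    ModelSpec,
    TruncatedNormalSpec,
    build_design_from_arrays,
    cov_from_param,
)
from .smc_evidence import SMCConfig, estimate_evidence

__all__ = ["load_radon", "build_radon_model", "aic", "radon_table",
            "RADON_MODELS"]

RADON_MODELS = ("M0", "M1", "M2", "M3", "M4", "M5")

_LOG_RADON_CANDIDATES = ("log_radon", "log radon", "lradon")
_ACTIVITY_CANDIDATES = ("activity", "radon")
_URANIUM_CANDIDATES = ("Uppm", "uranium_ppm", "u_ppm", "u")
_LOG_URANIUM_CANDIDATES = ("log_uranium", "log_u")


def _find_column(df: pd.DataFrame, candidates) -> str | None:
    for c in candidates:
        if c in df.columns:
            return c
    return None


def load_radon(path, county_col: str = "county",
               floor_col: str = "floor") -> tuple[pd.DataFrame, dict]:
    """Load and standardise a radon CSV.

    The file must provide a county label, a floor indicator in {0, 1}, the
    radon level (either already logged, in a ``log_radon``-style column, or
    raw in an ``activity`` column, which is then logged with zero activity
    floored at 0.1 as is conventional for this dataset), and a county
    uranium level (``Uppm``-style raw, logged on load, or pre-logged).

    Returns ``(table, summary)``: the table has columns ``county``,
    ``floor``, ``y`` (standardised log radon) and ``v`` (standardised
    county log uranium); the summary reports n, J, group-size extremes,
    the basement fraction, and the exact transforms applied.
    """
    df = pd.read_csv(path)
    for col in (county_col, floor_col):
        if col not in df.columns:
            raise ValueError(f"radon CSV lacks required column {col!r}")
    county = df[county_col].astype(str).str.strip()
    floor = df[floor_col].to_numpy()
    if not np.isin(floor, (0, 1)).all():
        raise ValueError("floor column must contain only 0 (basement) and 1")
    lr_col = _find_column(df, _LOG_RADON_CANDIDATES)
    if lr_col is not None:
        log_radon = df[lr_col].to_numpy(dtype=float)
        radon_transform = f"{lr_col} used as-is"
    else:
        act_col = _find_column(df, _ACTIVITY_CANDIDATES)
        if act_col is None:
            raise ValueError(
                "radon CSV needs a log-radon or activity column "
                f"(looked for {_LOG_RADON_CANDIDATES + _ACTIVITY_CANDIDATES})")
        act = df[act_col].to_numpy(dtype=float)
        log_radon = np.log(np.maximum(act, 0.1))
        radon_transform = f"log(max({act_col}, 0.1))"
    lu_col = _find_column(df, _LOG_URANIUM_CANDIDATES)
    if lu_col is not None:
        log_u = df[lu_col].to_numpy(dtype=float)
        uranium_transform = f"{lu_col} used as-is"
    else:
        u_col = _find_column(df, _URANIUM_CANDIDATES)
        if u_col is None:
            raise ValueError(
                "radon CSV needs a uranium column "
                f"(looked for {_URANIUM_CANDIDATES + _LOG_URANIUM_CANDIDATES})")
        log_u = np.log(df[u_col].to_numpy(dtype=float))
        uranium_transform = f"log({u_col})"
    if np.isnan(log_radon).any() or np.isnan(log_u).any():
        raise ValueError("missing values in radon or uranium columns")

    y = (log_radon - log_radon.mean()) / log_radon.std(ddof=1)
    # uranium is a county-level covariate: standardise across counties
    per_county = pd.Series(log_u).groupby(county.values).first()
    v_std = (per_county - per_county.mean()) / per_county.std(ddof=1)
    v = county.map(v_std).to_numpy(dtype=float)

    table = pd.DataFrame({
        "county": county.to_numpy(), "floor": floor.astype(int),
        "y": y, "v": v})
    sizes = table.groupby("county").size()
    summary = {
        "n": int(len(table)),
        "J": int(sizes.shape[0]),
        "max_group_size": int(sizes.max()),
        "min_group_size": int(sizes.min()),
        "basement_fraction": float((table["floor"] == 0).mean()),
        "radon_transform": radon_transform + ", then standardised (mean 0, sd 1)",
        "uranium_transform": uranium_transform
        + ", then standardised across counties",
    }
    return table, summary


def _county_info(table: pd.DataFrame):
    counties = list(dict.fromkeys(table["county"]))
    index = {c: j for j, c in enumerate(counties)}
    g = table["county"].map(index).to_numpy(dtype=np.intp)
    return counties, g


def build_radon_model(name: str, table: pd.DataFrame,
                      ) -> tuple[GroupedDesign, ModelSpec]:
    """Build the design matrix and model specification for one radon model."""
    if name not in RADON_MODELS:
        raise ValueError(f"unknown radon model {name!r}; choose from {RADON_MODELS}")
    y = table["y"].to_numpy(dtype=float)
    t = table["floor"].to_numpy(dtype=float)
    v = table["v"].to_numpy(dtype=float)
    counties, g = _county_info(table)
    J = len(counties)
    one_m_t = 1.0 - t
    ig = InverseGammaPrior(3.0, 1.0)

    def gaussian(d):
        return GaussianPrior(np.zeros(d), np.eye(d))

    if name == "M0":
        X = np.column_stack([one_m_t, t])
        spec = ModelSpec(kind="linear", name=name, coef_prior=gaussian(2),
                         noise_prior=ig, x_columns=("basement", "floor1"))
        return GroupedDesign(y=y, X=X), spec
    if name == "M1":
        X = np.column_stack([one_m_t, t, v])
        spec = ModelSpec(kind="linear", name=name, coef_prior=gaussian(3),
                         noise_prior=ig,
                         x_columns=("basement", "floor1", "log_uranium"))
        return GroupedDesign(y=y, X=X), spec
    if name == "M2":
        ind = np.zeros((len(y), J))
        ind[np.arange(len(y)), g] = 1.0
        X = np.column_stack([ind, one_m_t, t])
        names = tuple(f"county:{c}" for c in counties) + ("basement", "floor1")
        spec = ModelSpec(kind="linear", name=name, coef_prior=gaussian(J + 2),
                         noise_prior=ig, x_columns=names)
        return GroupedDesign(y=y, X=X), spec
    if name == "M3":
        has_floor1 = np.zeros(J, dtype=bool)
        np.logical_or.at(has_floor1, g, t > 0.5)
        keep = np.flatnonzero(has_floor1)
        a_cols = np.zeros((len(y), J))
        a_cols[np.arange(len(y)), g] = one_m_t
        b_cols = np.zeros((len(y), keep.size))
        for k, j in enumerate(keep):
            b_cols[:, k] = (g == j) * t
        X = np.column_stack([a_cols, b_cols])
        names = tuple(f"county:{c}:basement" for c in counties) + tuple(
            f"county:{counties[j]}:floor1" for j in keep)
        spec = ModelSpec(kind="linear", name=name,
                         coef_prior=gaussian(X.shape[1]), noise_prior=ig,
                         x_columns=names)
        return GroupedDesign(y=y, X=X), spec
    if name == "M4":
        X = np.column_stack([one_m_t, t, v])
        spec = ModelSpec(kind="multilevel_intercept", name=name,
                         coef_prior=gaussian(3), noise_prior=ig,
                         group_var_prior=ig,
                         x_columns=("basement", "floor1", "log_uranium"))
        return build_design_from_arrays(y, X, None, table["county"]), spec
    # M5
    X = np.column_stack([one_m_t, t, v])
    Z = np.column_stack([one_m_t, t])
    struct = CovarianceStructure(kind="pair_correlation", m=2,
                                 rho_prior=TruncatedNormalSpec(0.0, 1.0, -1.0, 1.0))
    spec = ModelSpec(kind="multilevel_general", name="M5",
                     coef_prior=gaussian(3), noise_prior=ig,
                     structure=struct, component_priors=(ig, ig),
                     x_columns=("basement", "floor1", "log_uranium"),
                     z_columns=("basement", "floor1"))
    return build_design_from_arrays(y, X, Z, table["county"]), spec


# --------------------------------------------------------------------------
# AIC
# --------------------------------------------------------------------------

def _profiled_marginal_negloglik(params, design, spec):
    """-log marginal likelihood maximised over beta by per-group GLS.

    ``params``: log variances (+ atanh rho for the pair-correlation
    structure).  Group effects are marginalised into blockwise covariances
    V_j = sigma_y^2 I + Z_j Sigma_eta Z_j'.
    """
    s2y = np.exp(params[0])
    if spec.kind == "multilevel_intercept":
        Sig_eta = np.array([[np.exp(params[1])]])
        Zfull = np.ones((design.n, 1))
    else:
        nvar = spec.structure.n_variance_components
        nu = list(np.exp(params[1:1 + nvar]))
        if spec.structure.fixed_rho is None and spec.structure.kind in (
                "pair_correlation", "banded_shared_rho"):
            nu.append(np.tanh(params[-1]))
        Sig_eta, ok = cov_from_param(spec.structure, np.asarray(nu))
        if not ok:
            return 1e100
        Zfull = design.Z
    logdet = 0.0
    XtX = np.zeros((design.d, design.d))
    Xty = np.zeros(design.d)
    whitened = []
    for j in range(design.J):
        rows = np.flatnonzero(design.group == j)
        Zj = Zfull[rows]
        Vj = s2y * np.eye(rows.size) + Zj @ Sig_eta @ Zj.T
        try:
            Lj = np.linalg.cholesky(Vj)
        except np.linalg.LinAlgError:
            return 1e100
        logdet += 2.0 * np.sum(np.log(np.diag(Lj)))
        Xw = np.linalg.solve(Lj, design.X[rows])
        yw = np.linalg.solve(Lj, design.y[rows])
        XtX += Xw.T @ Xw
        Xty += Xw.T @ yw
        whitened.append((Xw, yw))
    beta = np.linalg.solve(XtX, Xty)
    rss = sum(float((yw - Xw @ beta) @ (yw - Xw @ beta)) for Xw, yw in whitened)
    return 0.5 * (logdet + rss + design.n * np.log(2.0 * np.pi))


def aic(design: GroupedDesign, spec: ModelSpec) -> tuple[float, int]:
    """Akaike information criterion AIC = 2k - 2 max log likelihood.

    Single-level models: the ML fit is ordinary least squares with
    sigma2_hat = RSS / n, and k counts the identifiable coefficients
    (the matrix rank of X; redundant indicator columns do not count).
    Multilevel models: the group effects are marginalised into blockwise
    covariances and the resulting Gaussian likelihood is maximised by
    profiling beta through GLS and numerically optimising the variance
    parameters on the log scale; k is the coefficient count plus the
    number of variance-covariance parameters.
    """
    if spec.kind in ("linear", "linear_nig"):
        coef, rss, rank, _ = np.linalg.lstsq(design.X, design.y, rcond=None)
        resid = design.y - design.X @ coef
        rss = float(resid @ resid)
        sigma2_hat = rss / design.n
        max_ll = -0.5 * design.n * (np.log(2.0 * np.pi * sigma2_hat) + 1.0)
        k = int(rank)
        return float(2.0 * k - 2.0 * max_ll), k
    if spec.kind == "multilevel_intercept":
        n_var = 2
        x0s = [np.log([0.5, 0.1]), np.log([1.0, 1.0]), np.log([0.2, 0.5])]
    else:
        n_var = 1 + spec.structure.n_params
        base = np.concatenate([[np.log(0.5)],
                               np.log(np.full(spec.structure.n_variance_components, 0.2))])
        has_rho = (spec.structure.fixed_rho is None and spec.structure.kind in
                   ("pair_correlation", "banded_shared_rho"))
        if has_rho:
            base = np.concatenate([base, [0.0]])
        x0s = [base, base + 0.5, base - 0.5]
    best = None
    for x0 in x0s:
        res = minimize(_profiled_marginal_negloglik, x0,
                       args=(design, spec), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e99:
        raise RuntimeError("marginal ML optimisation failed for the "
                           f"{spec.kind} model: {best}")
    k = design.d + n_var
    return float(2.0 * k + 2.0 * best.fun), k


def radon_table(
    table: pd.DataFrame, smc: SMCConfig,
    models: Sequence[str] = RADON_MODELS,
    modes: Sequence[str] = ("integrated",),
) -> pd.DataFrame:
    """Model-comparison table: k, AIC and SMC evidence per radon model.

    Ranks are 1 = best (smallest AIC; largest evidence) within each column.
    """
    rows = []
    for name in models:
        design, spec = build_radon_model(name, table)
        value, k = aic(design, spec)
        row = {"model": name, "k": k, "aic": value}
        for mode in modes:
            est = estimate_evidence(design, spec, replace(smc, mode=mode))
            row[f"log_evidence_{mode}"] = est.log_evidence_mean
            row[f"sd_{mode}"] = est.log_evidence_sd
        rows.append(row)
    out = pd.DataFrame(rows)
    out["aic_rank"] = out["aic"].rank(method="min").astype(int)
    for mode in modes:
        out[f"rank_{mode}"] = (
            out[f"log_evidence_{mode}"].rank(ascending=False, method="min")
            .astype(int))
    return out
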