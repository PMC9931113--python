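"""Serialisation: dataset CSVs, YAML model specifications, JSON results.

Conventions: data travel as CSV (header row, UTF-8, '.' decimal) with
columns ``y``, ``group``, optionally ``t``, and design columns ``x_1..x_d``
/ ``z_1..z_m``; model specifications are human-editable YAML; results are
JSON validated against a small versioned schema.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model_spec import (
    CovarianceStructure,
    GaussianPrior,
    GroupedDesign,
    InverseGammaPrior,
    ModelSpec,
    NIGPrior,
    TruncatedNormalSpec,
    build_design,
)

RESULT_SCHEMA_VERSION = "1"

__all__ = [
    "write_dataset_csv",
    "read_dataset_csv",
    "model_spec_from_yaml",
    "write_result",
    "validate_result",
    "RESULT_SCHEMA_VERSION",
]


def write_dataset_csv(design: GroupedDesign, path, t=None) -> None:
    """Write a dataset as CSV (columns y, group, [t], x_1.., [z_1..])."""
    data = {"y": design.y,
            "group": np.asarray(design.group_labels, dtype=object)[design.group]}
    if t is not None:
        data["t"] = np.asarray(t, dtype=float)
    for i in range(design.d):
        data[f"x_{i+1}"] = design.X[:, i]
    for i in range(design.m):
        data[f"z_{i+1}"] = design.Z[:, i]
    # %.17g round-trips float64 exactly through text
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_dataset_csv(path) -> tuple[GroupedDesign, np.ndarray | None]:
    """Read a dataset CSV back into a :class:`GroupedDesign` (and t if present)."""
    df = pd.read_csv(path, float_precision="round_trip")
    x_cols = sorted((c for c in df.columns if c.startswith("x_")),
                    key=lambda c: int(c.split("_")[1]))
    z_cols = sorted((c for c in df.columns if c.startswith("z_")),
                    key=lambda c: int(c.split("_")[1]))
    if "y" not in df.columns or not x_cols:
        raise ValueError("dataset CSV needs a 'y' column and x_1..x_d columns")
    group = "group" if "group" in df.columns else None
    design = build_design(df, outcome="y", covariates=x_cols, group=group,
                          z_covariates=z_cols)
    t = df["t"].to_numpy(dtype=float) if "t" in df.columns else None
    return design, t


# --------------------------------------------------------------------------
# YAML model specifications
# --------------------------------------------------------------------------

def _coef_covariance(entry, d: int) -> np.ndarray:
    if entry is None or entry == "identity":
        return np.eye(d)
    if isinstance(entry, Mapping):
        if "scale_identity" in entry:
            return float(entry["scale_identity"]) * np.eye(d)
        if "diagonal" in entry:
            diag = np.asarray(entry["diagonal"], dtype=float)
            if diag.shape != (d,):
                raise ValueError(f"diagonal covariance needs {d} entries")
            return np.diag(diag)
        if "matrix" in entry:
            return np.asarray(entry["matrix"], dtype=float)
    raise ValueError(f"unrecognised coefficient covariance spec: {entry!r}")


def _ig(entry, what: str) -> InverseGammaPrior:
    try:
        return InverseGammaPrior(float(entry["a"]), float(entry["b"]))
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{what} needs a mapping with keys a, b") from exc


def model_spec_from_yaml(source, d: int, m: int = 0) -> ModelSpec:
    """Build a :class:`ModelSpec` from YAML (path, stream, or parsed dict).

    ``d`` (and ``m`` for general multilevel models) come from the data the
    spec will be applied to.  See the repository README for the schema.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    kind = doc.get("kind")
    name = doc.get("name", "")
    coef = doc.get("coefficients", {}) or {}
    mean = coef.get("mean", 0.0)
    mu = np.full(d, float(mean)) if np.isscalar(mean) else np.asarray(mean, float)
    Sigma = _coef_covariance(coef.get("covariance"), d)
    if kind == "linear_nig":
        nig = doc.get("nig", {})
        prior = NIGPrior(a=float(nig.get("a", 3.0)), b=float(nig.get("b", 1.0)),
                         mu=mu, Sigma=Sigma, gamma=float(nig.get("gamma", 1.0)))
        return ModelSpec(kind=kind, name=name, coef_prior=prior)
    coef_prior = GaussianPrior(mu, Sigma)
    noise = _ig(doc.get("noise", {"a": 3, "b": 1}), "noise")
    if kind == "linear":
        return ModelSpec(kind=kind, name=name, coef_prior=coef_prior,
                         noise_prior=noise)
    if kind == "multilevel_intercept":
        gv = _ig(doc.get("group_variance", {"a": 3, "b": 1}), "group_variance")
        return ModelSpec(kind=kind, name=name, coef_prior=coef_prior,
                         noise_prior=noise, group_var_prior=gv)
    if kind == "multilevel_general":
        sdoc = doc.get("structure", {}) or {}
        m_eff = int(sdoc.get("m", m))
        if m_eff <= 0:
            raise ValueError("multilevel_general needs structure.m or data with z columns")
        rho_prior = None
        if "rho_prior" in sdoc:
            rp = sdoc["rho_prior"] or {}
            rho_prior = TruncatedNormalSpec(
                mean=float(rp.get("mean", 0.0)), sd=float(rp.get("sd", 1.0)),
                lower=float(rp.get("lower", -1.0)), upper=float(rp.get("upper", 1.0)))
        struct = CovarianceStructure(
            kind=sdoc.get("kind", "diagonal"), m=m_eff, rho_prior=rho_prior,
            fixed_rho=(None if sdoc.get("fixed_rho") is None
                       else float(sdoc["fixed_rho"])))
        comp = sdoc.get("components", {"a": 3, "b": 1})
        if isinstance(comp, Mapping):
            comps = tuple(_ig(comp, "components")
                          for _ in range(struct.n_variance_components))
        else:
            comps = tuple(_ig(c, "components") for c in comp)
        return ModelSpec(kind=kind, name=name, coef_prior=coef_prior,
                         noise_prior=noise, structure=struct,
                         component_priors=comps)
    raise ValueError(f"unknown model kind in YAML: {kind!r}")


# --------------------------------------------------------------------------
# JSON results
# --------------------------------------------------------------------------

def write_result(path, payload: dict, seed: int | None = None,
                 config: dict | None = None) -> dict:
    """Write a result JSON with schema version, seed and config embedded."""
    from . import __version__

    doc = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": config or {},
        **payload,
    }
    validate_result(doc)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")
    return doc


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def validate_result(doc: dict) -> None:
    """Check a result document against the (minimal, versioned) schema."""
    if not isinstance(doc, dict):
        raise ValueError("result must be a JSON object")
    for key in ("schema_version", "package_version", "seed", "config"):
        if key not in doc:
            raise ValueError(f"result document lacks required key {key!r}")
    if doc["schema_version"] != RESULT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported result schema version {doc['schema_version']!r}")
    if not isinstance(doc["config"], dict):
        raise ValueError("config must be an object")
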