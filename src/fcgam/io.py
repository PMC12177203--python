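"""Dataset readers/writers, configuration loading and result serialization.

Datasets travel as comma-separated text with a header row (UTF-8, '.'
decimal).  Loading is complete-case: rows with missing, non-numeric or
nonpositive outcome values are rejected with a per-row reason log and a
summary count, mirroring how such records are handled in observational
biomarker studies.  Fits are serialized to a versioned JSON schema from
which prediction can be resumed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .regression import CoefficientVector, FitResult, ModelSpec, PairedDataset

__all__ = [
    "SPEC_VERSION",
    "DataLoadError",
    "read_paired_csv",
    "write_dataset_csv",
    "fit_to_json",
    "fit_report",
    "load_fit_json",
    "load_config",
]

SPEC_VERSION = "1.0"
log = logging.getLogger("fcgam")


class DataLoadError(ValueError):
    """Raised when a dataset file cannot be turned into a valid PairedDataset."""


def read_paired_csv(path, u_col: str, v_col: str, covariate_cols) -> PairedDataset:
    """Load a paired-outcome dataset from CSV, dropping invalid rows.

    Rows with missing values in any used column, or with nonpositive outcome
    values, are excluded; each exclusion is logged with its row index and
    reason, and the summary count is logged once.
    """
    path = Path(path)
    if not path.exists():
        raise DataLoadError(f"file not found: {path}")
    covariate_cols = list(covariate_cols)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataLoadError(f"empty file: {path}") from exc
    missing = [c for c in [u_col, v_col, *covariate_cols] if c not in frame.columns]
    if missing:
        raise DataLoadError(f"missing columns {missing} in {path} "
                            f"(found {list(frame.columns)})")
    used = frame[[u_col, v_col, *covariate_cols]].apply(pd.to_numeric, errors="coerce")

    keep = np.ones(len(used), dtype=bool)
    for idx, row in used.iterrows():
        if row.isna().any():
            bad = list(row.index[row.isna()])
            log.warning("row %d excluded: non-numeric or missing value in %s", idx, bad)
            keep[idx] = False
        elif row[u_col] <= 0 or row[v_col] <= 0:
            log.warning("row %d excluded: nonpositive outcome (u=%s, v=%s)",
                        idx, row[u_col], row[v_col])
            keep[idx] = False
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("excluded %d of %d rows during load", n_dropped, len(used))
    used = used[keep]
    if used.empty:
        raise DataLoadError(f"no valid data rows in {path}")
    return PairedDataset(
        u=used[u_col].to_numpy(), v=used[v_col].to_numpy(),
        covariates=used[covariate_cols].to_numpy(),
        covariate_names=tuple(covariate_cols))


def write_dataset_csv(path, data: PairedDataset, u_col: str = "u", v_col: str = "v"):
    frame = pd.DataFrame({u_col: data.u, v_col: data.v})
    for j, name in enumerate(data.covariate_names):
        frame[name] = data.covariates[:, j]
    frame.to_csv(path, index=False)


def fit_report(fit: FitResult, intervals=None) -> dict:
    """JSON-serializable summary of a fit (coefficients, BIC, convergence)."""
    est = fit.estimate
    report = {
        "spec_version": SPEC_VERSION,
        "model": {
            "covariate_names": list(fit.spec.covariate_names),
            "theta_mode": fit.spec.theta_mode,
        },
        "coefficients": {
            "beta_u": est.beta_u.tolist(),
            "beta_v": est.beta_v.tolist(),
            "beta_theta": est.beta_theta.tolist(),
            "beta_lambda": est.lambda_coefficients.tolist(),
            "shape_u": float(est.shape_u),
            "shape_v": float(est.shape_v),
        },
        "kendall_tau_at_intercept": fit.kendall_tau_at_intercept,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "optimizer_message": fit.message,
    }
    if intervals is not None:
        report["credible_intervals"] = {
            "level": intervals.attrs.get("level"),
            "table": intervals.reset_index().to_dict(orient="records"),
        }
    return report


def fit_to_json(path, fit: FitResult, intervals=None):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit_report(fit, intervals), fh, indent=2)


def load_fit_json(path):
    """Reload (CoefficientVector, ModelSpec) from a serialized fit report."""
    with open(path, encoding="utf-8") as fh:
        report = json.load(fh)
    spec = ModelSpec(covariate_names=tuple(report["model"]["covariate_names"]),
                     theta_mode=report["model"]["theta_mode"])
    c = report["coefficients"]
    gamma = CoefficientVector(
        beta_u=np.asarray(c["beta_u"]), beta_v=np.asarray(c["beta_v"]),
        beta_theta=np.asarray(c["beta_theta"]),
        shape_u=c["shape_u"], shape_v=c["shape_v"])
    return gamma, spec


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
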