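"""Shared numerical helpers: vectorized covariate-adjusted OLS and design building.

All association operations in this package reduce to ordinary least squares of a
quantitative phenotype on a predictor of interest plus nuisance covariates. For
scans over many predictors we residualize phenotype and predictors on the
covariates once (Frisch-Waugh-Lovell), which is exact and orders of magnitude
faster than refitting the full design per variant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ols_scan", "ols_single", "build_covariates"]


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept + covariates as a float array; categoricals are dummy-coded."""
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        covariates = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"covariate rows ({X.shape[0]}) != phenotype length ({n})")
    return np.column_stack([np.ones(n), X])


def ols_scan(
    y: np.ndarray,
    predictors: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-column OLS of ``y`` on each predictor, adjusting for covariates.

    Parameters
    ----------
    y : (n,) response.
    predictors : (n, m) matrix; each column is tested separately.
    covariates : optional nuisance design (an intercept is always included).

    Returns
    -------
    DataFrame with columns beta, se, p, n, and ``skipped`` (True when the
    residualized predictor is numerically constant, e.g. a monomorphic variant
    or one collinear with the covariates).
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(predictors, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = y.shape[0]
    X = _design_matrix(covariates, n)
    k = np.linalg.matrix_rank(X)
    if k >= n - 1:
        raise ValueError("covariate design leaves no residual degrees of freedom")

    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    s_gg = np.einsum("ij,ij->j", G_r, G_r)
    s_gy = G_r.T @ y_r
    s_yy = float(y_r @ y_r)

    skipped = s_gg <= 1e-10 * max(1.0, np.abs(G).max() ** 2)
    s_gg_safe = np.where(skipped, 1.0, s_gg)
    beta = s_gy / s_gg_safe
    df = n - k - 1
    rss = np.maximum(s_yy - beta**2 * s_gg_safe, 0.0)
    se = np.sqrt(rss / df / s_gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "beta": np.where(skipped, np.nan, beta),
            "se": np.where(skipped, np.nan, se),
            "p": np.where(skipped, np.nan, p),
            "n": n,
            "skipped": skipped,
        }
    )
    return out


def ols_single(
    y: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Single-predictor convenience wrapper around :func:`ols_scan`."""
    row = ols_scan(y, np.asarray(predictor, dtype=float)[:, None], covariates).iloc[0]
    return {
        "beta": float(row.beta),
        "se": float(row.se),
        "p": float(row.p),
        "n": int(row.n),
        "skipped": bool(row.skipped),
    }


def build_covariates(
    cohort: pd.DataFrame,
    ancestry_pcs: int = 4,
    include_site: bool = True,
    include_plate: bool = False,
    include_smoking: bool = False,
    extra: Sequence[str] = (),
) -> pd.DataFrame:
    """Assemble the standard nuisance design from a cohort table.

    Age, sex and age^2 are always included; ancestry PCs, sequencing site,
    genotyping plate and smoking covariates (ever-smoked + pack-years) are
    optional blocks matching the covariate sets used by the different
    association stages.
    """
    cols = {
        "age": cohort["age"].to_numpy(dtype=float),
        "sex": cohort["sex"].to_numpy(dtype=float),
        "age2": cohort["age"].to_numpy(dtype=float) ** 2,
    }
    for i in range(1, ancestry_pcs + 1):
        cols[f"ancestry_pc{i}"] = cohort[f"ancestry_pc{i}"].to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=cohort.index)
    if include_site and "sequencing_site" in cohort:
        out["sequencing_site"] = cohort["sequencing_site"].astype("category")
    if include_plate and "genotyping_plate" in cohort:
        out["genotyping_plate"] = cohort["genotyping_plate"].astype("category")
    if include_smoking:
        out["ever_smoked"] = cohort["ever_smoked"].to_numpy(dtype=float)
        out["pack_years"] = cohort["pack_years"].to_numpy(dtype=float)
    for name in extra:
        out[name] = cohort[name]
    return out
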