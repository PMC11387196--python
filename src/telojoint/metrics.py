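"""The joint PC1/PC2 telomere-length metric and its diagnostics.

Both telomere measurements (qPCR T:S ratio and coverage-corrected TelSeq) are
rank-based inverse-normal transformed (INT) and combined by a two-variable
PCA. Because both inputs have unit variance after INT, PCA on the covariance
equals PCA on the correlation matrix, so the variance shares have the closed
form ((1+|r|)/2, (1-|r|)/2) in the Pearson correlation r. PC1 captures the
shared (biological) telomere signal -- it is essentially the standardized
mean of the two metrics -- while PC2 captures their discordance and is used
downstream to flag metric-specific (artifact-prone) associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "inverse_normal_transform",
    "combine_pca",
    "variance_share_closed_form",
    "TLMetricTable",
    "build_joint_metric",
    "age_prediction_benchmark",
    "joint_age_model_vif",
    "measurement_diagnostics",
]


def inverse_normal_transform(x, c: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transform with offset ``c`` (Blom by default).

    z_i = Phi^{-1}((rank_i - c) / (n - 2c + 1)), with average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if not 0 <= c <= 0.5:
        raise ValueError("offset c must lie in [0, 0.5]")
    if np.ptp(x) == 0:
        raise ValueError("all values equal: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    q = (ranks - c) / (x.size - 2 * c + 1)
    return stats.norm.ppf(q)


def variance_share_closed_form(r: float) -> tuple[float, float]:
    """Variance shares of the two principal axes of a 2x2 correlation matrix.

    The eigenvalues of [[1, r], [r, 1]] are 1 +/- |r|; divided by the trace 2
    this gives shares ((1 + |r|)/2, (1 - |r|)/2).
    """
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return (1 + abs(r)) / 2, (1 - abs(r)) / 2


@dataclass
class TLMetricTable:
    """Per-sample telomere metrics plus the global PCA summary."""

    table: pd.DataFrame  # qpcr_int, telseq_int, pc1, pc2 (+ raw columns if known)
    loadings: np.ndarray  # 2x2, columns = axes, rows = (qpcr, telseq)
    variance_explained: tuple[float, float]
    correlation: float


def combine_pca(qpcr_int, telseq_int) -> TLMetricTable:
    """Combine the two INT metrics by PCA of their 2x2 sample covariance.

    Axis signs are fixed for reproducibility: PC1 loads positively on both
    inputs and PC2 loads positively on qPCR (so pc2 tracks qpcr - telseq up
    to scale). Perfectly anti-correlated inputs admit no such orientation
    and raise.
    """
    q = np.asarray(qpcr_int, dtype=float)
    t = np.asarray(telseq_int, dtype=float)
    if q.shape != t.shape or q.size < 3:
        raise ValueError("inputs must be same-length vectors of size >= 3")
    M = np.column_stack([q, t])
    Mc = M - M.mean(axis=0)
    S = np.cov(Mc, rowvar=False)
    r = float(np.corrcoef(q, t)[0, 1])
    if r <= -1 + 1e-12:
        raise ValueError(
            "inputs are perfectly anti-correlated: PC1 cannot load positively "
            "on both metrics; check the sign convention of the inputs"
        )
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # orientation: PC1 positive on both (sum positive), PC2 positive on qPCR
    if evecs[:, 0].sum() < 0:
        evecs[:, 0] = -evecs[:, 0]
    if evecs[0, 1] < 0:
        evecs[:, 1] = -evecs[:, 1]
    scores = Mc @ evecs
    shares = tuple(evals / evals.sum())
    table = pd.DataFrame(
        {"qpcr_int": q, "telseq_int": t, "pc1": scores[:, 0], "pc2": scores[:, 1]}
    )
    return TLMetricTable(table, evecs, shares, r)


def build_joint_metric(
    qpcr_raw, telseq_adjusted, c: float = 0.375, sample_id=None
) -> TLMetricTable:
    """INT both raw metrics, run the two-metric PCA and assemble the table."""
    q_int = inverse_normal_transform(qpcr_raw, c=c)
    t_int = inverse_normal_transform(telseq_adjusted, c=c)
    res = combine_pca(q_int, t_int)
    res.table.insert(0, "qpcr_raw", np.asarray(qpcr_raw, dtype=float))
    res.table.insert(1, "telseq_adjusted", np.asarray(telseq_adjusted, dtype=float))
    if sample_id is not None:
        res.table.insert(0, "sample_id", np.asarray(sample_id))
    return res


def age_prediction_benchmark(
    metrics: pd.DataFrame,
    age,
    n_train: int = 10_000,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap age-prediction RMSE for each candidate telomere metric.

    Per replicate, ``n_train`` individuals are drawn with replacement as the
    training set; a simple linear model age ~ metric is fit and evaluated
    (RMSE) on the individuals not drawn. Returns an (n_reps x metrics) frame
    of RMSEs. All metrics share the same resamples, so paired comparisons
    across metrics are meaningful.
    """
    age = np.asarray(age, dtype=float)
    n = age.size
    if n_train >= n:
        raise ValueError("n_train must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    out = np.empty((n_reps, metrics.shape[1]))
    cols = list(metrics.columns)
    M = metrics.to_numpy(dtype=float)
    for rep in range(n_reps):
        train = rng.integers(0, n, size=n_train)
        mask = np.ones(n, dtype=bool)
        mask[train] = False
        for j in range(M.shape[1]):
            x_tr, y_tr = M[train, j], age[train]
            slope, intercept = np.polyfit(x_tr, y_tr, 1)
            pred = intercept + slope * M[mask, j]
            out[rep, j] = np.sqrt(np.mean((age[mask] - pred) ** 2))
    return pd.DataFrame(out, columns=cols)


def joint_age_model_vif(age, telseq_int, qpcr_int, sex) -> dict:
    """Fit age ~ telseq + qpcr + sex; report VIFs and per-metric delta-R^2.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing predictor j on
    the remaining predictors; delta-R^2 is the drop in model R^2 when one
    telomere metric is removed.
    """
    age = np.asarray(age, dtype=float)
    X = pd.DataFrame(
        {
            "telseq": np.asarray(telseq_int, dtype=float),
            "qpcr": np.asarray(qpcr_int, dtype=float),
            "sex": np.asarray(sex, dtype=float),
        }
    )
    if len(X) <= 10:
        raise ValueError("need more than 10 observations")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("singular design")
    full = sm.OLS(age, Xc).fit()
    vif = {}
    for j, name in enumerate(X.columns):
        others = sm.add_constant(X.drop(columns=name))
        r2 = sm.OLS(X[name], others).fit().rsquared
        vif[name] = 1.0 / (1.0 - r2)
    delta_r2 = {}
    for name in ("telseq", "qpcr"):
        red = sm.OLS(age, sm.add_constant(X.drop(columns=name))).fit()
        delta_r2[name] = full.rsquared - red.rsquared
    return {"vif": vif, "r2": full.rsquared, "delta_r2": delta_r2, "model": full}


def measurement_diagnostics(
    qpcr_int,
    telseq_int,
    strata: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    outlier_z: float = 1.96,
) -> dict:
    """Bland-Altman agreement summary plus an outlier-status logistic model.

    The paired difference is qpcr - telseq; bias is its mean and the limits
    of agreement are bias +/- 1.96 SD. A sample is an outlier when its
    difference deviates from the bias by more than ``outlier_z`` SDs. When
    covariates (e.g. carrier flags for a suspected reference-gene artifact)
    are supplied, outlier status is regressed on them by logistic regression
    and per-covariate odds ratios are reported.
    """
    q = np.asarray(qpcr_int, dtype=float)
    t = np.asarray(telseq_int, dtype=float)
    diff = q - t
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    outlier = np.abs(diff - bias) > outlier_z * sd if sd > 0 else np.zeros_like(diff, bool)
    result = {
        "bias": bias,
        "sd": sd,
        "limits_of_agreement": loa,
        "n_outliers": int(outlier.sum()),
        "outlier": outlier,
    }
    if strata is not None:
        per = []
        for col in strata.columns:
            for level, idx in strata.groupby(col).groups.items():
                d = diff[np.asarray(idx)]
                per.append(
                    {"stratum": f"{col}={level}", "bias": float(d.mean()),
                     "sd": float(d.std(ddof=1)) if d.size > 1 else np.nan, "n": d.size}
                )
        result["strata"] = pd.DataFrame(per)
    if covariates is not None:
        Xl = sm.add_constant(covariates.astype(float))
        fit = sm.Logit(outlier.astype(float), Xl).fit(disp=False)
        result["logistic"] = pd.DataFrame(
            {
                "or": np.exp(fit.params.drop("const")),
                "p": fit.pvalues.drop("const"),
            }
        )
    return result
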