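"""Coverage-PC correction of WGS telomere-length estimates.

TelSeq-style estimators count telomeric reads, so anything that perturbs
genome-wide coverage (library prep, flow cell, pipeline version) leaks into
the telomere estimate. The correction here mirrors the quantized-coverage
strategy used at biobank scale:

1. the genome is tiled into 1-kb windows and tiles overlapping mappability
   blacklists, known structural variants, or non-autosomal contigs are
   dropped;
2. per-sample mean depth per kept tile is reconstructed from quantized
   (binned) depth intervals, each base contributing the representative
   (median) depth of its bin;
3. samples are partitioned into randomized batches, the top principal
   components of each batch's (column-centered) coverage matrix are
   estimated by randomized PCA, and the raw telomere estimate is replaced by
   its residual after regression on those PC scores.

The default parameters use four depth bins (0-9, 10-19, 20-49, 50+), 300 PCs
and batches of 20,000 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .utils import ols_scan

__all__ = [
    "CorrectionParams",
    "DEFAULT_AUTOSOMES",
    "make_tiles",
    "filter_tiles",
    "reconstruct_depth",
    "batch_pca_residualize",
    "association_with_seq_metrics",
]

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class CorrectionParams:
    """Parameters of the quantized-depth reconstruction and PC correction.

    ``depth_bin_edges`` partition [0, inf) into half-open intervals; the
    closed bins use the median of their integer depth range as
    representative (4.5, 14.5, 34.5). The open top bin (50+) has no defined
    median, so a fixed representative (default 60) is used; since the PCA
    operates on the reconstructed matrix, the correction is insensitive to
    this choice as long as ordering is preserved.
    """

    depth_bin_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 50.0)
    bin_representatives: tuple[float, ...] = (4.5, 14.5, 34.5, 60.0)
    n_pcs: int = 300
    batch_size: int = 20_000
    seed: int = 0
    tile_size: int = 1000
    autosomes: tuple[str, ...] = field(default=DEFAULT_AUTOSOMES)

    def __post_init__(self):
        if len(self.bin_representatives) != len(self.depth_bin_edges):
            raise ValueError("one representative per depth bin required")
        if any(
            b >= a
            for a, b in zip(self.bin_representatives[1:], self.bin_representatives[:-1])
        ):
            raise ValueError("bin representatives must be strictly increasing")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")


def make_tiles(chrom_sizes: dict[str, int], tile_size: int = 1000) -> pd.DataFrame:
    """1-kb (by default) non-overlapping tiles, 0-based half-open."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, tile_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + tile_size, size))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def filter_tiles(
    tiles: pd.DataFrame,
    masks: dict[str, pd.DataFrame] | None = None,
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
) -> pd.DataFrame:
    """Mark tiles dropped by any mask overlap (>= 1 base) or non-autosomal contig.

    ``masks`` maps a reason code (e.g. ``mappability``, ``blacklist``, ``sv``)
    to a BED-like frame (chrom, start, end) in 0-based half-open coordinates.
    Returns the tile frame with ``kept`` and ``reason`` columns.
    """
    tiles = tiles.copy().reset_index(drop=True)
    known = set(autosomes) | {"chrX", "chrY", "chrM"}
    reason = np.array([""] * len(tiles), dtype=object)
    non_auto = ~tiles["chrom"].isin(autosomes).to_numpy()
    reason[non_auto] = "non-autosome"
    for name, bed in (masks or {}).items():
        unknown = set(bed["chrom"]) - known
        if unknown:
            raise ValueError(f"mask '{name}' has unknown contigs: {sorted(unknown)}")
        for chrom, grp in bed.groupby("chrom"):
            sel = (tiles["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            t_start = tiles.loc[sel, "start"].to_numpy()[:, None]
            t_end = tiles.loc[sel, "end"].to_numpy()[:, None]
            hit = ((t_start < ends[None, :]) & (t_end > starts[None, :])).any(axis=1)
            idx = np.flatnonzero(sel)[hit]
            blank = reason[idx] == ""
            reason[idx[blank]] = name
    tiles["kept"] = reason == ""
    tiles["reason"] = reason
    return tiles


def reconstruct_depth(
    quantized: pd.DataFrame,
    tiles: pd.DataFrame,
    params: CorrectionParams | None = None,
    on_uncovered: str = "error",
) -> pd.DataFrame:
    """Reconstruct per-sample mean depth per kept tile from quantized intervals.

    ``quantized`` is a mosdepth-style long table (sample_id, chrom, start,
    end, bin) where ``bin`` indexes the depth bin (0..3 by default) or is a
    label like ``"0:10"``/``"50:inf"``. Each base of a tile contributes its
    interval's representative depth; the tile value is the mean over bases.

    Uncovered tile bases raise by default; ``on_uncovered="zero"`` fills them
    with depth 0 (and warns).
    """
    params = params or CorrectionParams()
    kept = tiles[tiles["kept"]] if "kept" in tiles else tiles
    if len(kept) == 0:
        raise ValueError("no kept tiles to reconstruct")
    reps = np.asarray(params.bin_representatives)
    edges = np.asarray(params.depth_bin_edges)

    def _bin_rep(label) -> float:
        if isinstance(label, (int, np.integer)) and 0 <= label < len(reps):
            return float(reps[label])
        lo = float(str(label).split(":")[0])
        j = int(np.searchsorted(edges, lo, side="right") - 1)
        return float(reps[j])

    samples = list(dict.fromkeys(quantized["sample_id"]))
    covered = np.zeros((len(samples), len(kept)))
    acc = np.zeros((len(samples), len(kept)))
    srow = {s: i for i, s in enumerate(samples)}
    kept_rows = kept.reset_index(drop=True)
    for rec in quantized.itertuples(index=False):
        rep = _bin_rep(rec.bin)
        i = srow[rec.sample_id]
        sel = kept_rows[(kept_rows["chrom"] == rec.chrom)]
        for j, t in zip(sel.index, sel.itertuples(index=False)):
            ov = min(rec.end, t.end) - max(rec.start, t.start)
            if ov > 0:
                acc[i, j] += rep * ov
                covered[i, j] += ov
    widths = (kept_rows["end"] - kept_rows["start"]).to_numpy()
    full = covered == widths[None, :]
    if not full.all():
        if on_uncovered == "zero":
            warnings.warn("uncovered tile bases filled with depth 0")
        else:
            missing = np.argwhere(~full)[0]
            raise ValueError(
                f"sample {samples[missing[0]]} leaves tile "
                f"{kept_rows.iloc[missing[1]]['chrom']}:{kept_rows.iloc[missing[1]]['start']} "
                "partially uncovered"
            )
    out = acc / widths[None, :]
    cols = [f"{c}:{s}-{e}" for c, s, e in zip(kept_rows["chrom"], kept_rows["start"], kept_rows["end"])]
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "sample_id", samples)
    return df


def _pc_scores(Xc: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Top-k principal component scores of a column-centered matrix.

    For matrices with few enough columns the scores come from an exact
    eigendecomposition of the Gram matrix X'X (cheapest and bit-stable);
    very wide matrices fall back to randomized SVD. Both agree with exact
    SVD to the accuracy the correction requires; components with negligible
    singular value are dropped.
    """
    n, m = Xc.shape
    if m <= 3000 or m <= 2 * k:
        G = Xc.T @ Xc
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1][:k]
        evals, evecs = evals[order], evecs[:, order]
        good = evals > max(evals[0], 0) * 1e-12
        return Xc @ evecs[:, good]
    U, S, _ = randomized_svd(
        Xc, n_components=k, n_oversamples=20, n_iter=7, random_state=seed
    )
    good = S > S[0] * 1e-12 if S[0] > 0 else np.zeros_like(S, dtype=bool)
    return U[:, good] * S[good]


def _coverage_values(cov: pd.DataFrame) -> np.ndarray:
    cols = [c for c in cov.columns if c not in ("sample_id", "batch")]
    return cov[cols].to_numpy(dtype=float)


def batch_pca_residualize(
    coverage: pd.DataFrame,
    telseq_raw: np.ndarray | pd.Series,
    params: CorrectionParams | None = None,
    return_scores: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Residualize the raw telomere estimate on per-batch coverage PCs.

    Samples are randomly partitioned into batches of ``params.batch_size``
    (the last batch absorbs the remainder). Within each batch the coverage
    columns are centered, the top ``min(n_pcs, batch_n - 1, n_tiles)`` PCs
    are estimated by randomized SVD, and the telomere estimate is regressed
    (with intercept) on the PC scores; the residual is the corrected value.

    Returns a frame (sample_id, telseq_raw, telseq_adjusted, batch) aligned
    to the input order; no sample is dropped.
    """
    params = params or CorrectionParams()
    X = _coverage_values(coverage)
    y = np.asarray(telseq_raw, dtype=float)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("telseq_raw not aligned with coverage matrix")
    rng = np.random.default_rng(params.seed)
    order = rng.permutation(n)
    n_batches = max(n // params.batch_size, 1)
    batch = np.empty(n, dtype=int)
    bounds = [i * params.batch_size for i in range(n_batches)] + [n]
    for b in range(n_batches):
        batch[order[bounds[b] : bounds[b + 1]]] = b

    adjusted = np.empty(n)
    batch_scores: dict[int, np.ndarray] = {}
    for b in range(n_batches):
        idx = np.flatnonzero(batch == b)
        Xb = X[idx]
        yb = y[idx]
        Xb = Xb - Xb.mean(axis=0)
        rank_cap = min(len(idx) - 1, Xb.shape[1])
        k = min(params.n_pcs, rank_cap)
        if k < params.n_pcs:
            warnings.warn(
                f"batch {b}: requested {params.n_pcs} PCs truncated to {k} (rank limit)"
            )
        if k == 0 or not np.any(Xb):
            if np.ptp(Xb) == 0 and params.n_pcs > 0 and Xb.size:
                warnings.warn("zero-variance coverage matrix; returning centered input")
            adjusted[idx] = yb - yb.mean()
            continue
        scores = _pc_scores(Xb, k, params.seed + b)
        batch_scores[b] = scores
        if scores.shape[1] == 0:
            adjusted[idx] = yb - yb.mean()
            continue
        design = np.column_stack([np.ones(len(idx)), scores])
        coef, *_ = np.linalg.lstsq(design, yb, rcond=None)
        adjusted[idx] = yb - design @ coef

    out = pd.DataFrame(
        {
            "sample_id": coverage["sample_id"].to_numpy()
            if "sample_id" in coverage
            else np.arange(n),
            "telseq_raw": y,
            "telseq_adjusted": adjusted,
            "batch": batch,
        }
    )
    if return_scores:
        return out, batch_scores
    return out


def association_with_seq_metrics(
    metrics: pd.DataFrame,
    tl_estimates: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Univariate association of each sequencing metric with each TL estimate.

    Metrics are standardized to unit SD before fitting (so slopes are per-SD
    of the metric); constant metrics are flagged and skipped. ``tl_estimates``
    may be a single vector or a frame of named estimates.
    """
    if not isinstance(tl_estimates, pd.DataFrame):
        tl_estimates = pd.DataFrame({"tl": np.asarray(tl_estimates, dtype=float)})
    rows = []
    for mname in metrics.columns:
        x = metrics[mname].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            for tname in tl_estimates.columns:
                rows.append(
                    {"metric": mname, "tl_metric": tname, "beta": np.nan, "se": np.nan,
                     "p": np.nan, "skipped": True}
                )
            continue
        z = (x - x.mean()) / sd
        for tname in tl_estimates.columns:
            res = ols_scan(tl_estimates[tname].to_numpy(dtype=float), z[:, None]).iloc[0]
            rows.append(
                {"metric": mname, "tl_metric": tname, "beta": res.beta, "se": res.se,
                 "p": res.p, "skipped": False}
            )
    return pd.DataFrame(rows)
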