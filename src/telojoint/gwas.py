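"""Per-variant association, QC, locus definition, fine-mapping, prioritization.

The association core is ordinary least squares of an INT-scale phenotype on
dosage plus nuisance covariates (age, sex, plate/site, ancestry PCs). In
unrelated synthetic cohorts this matches what a whole-genome mixed model
would estimate, without the machinery; the interface accepts any phenotype
vector so a mixed-model backend could be substituted.

Loci are defined by padding genome-wide-significant variants by +/-1 Mb,
substituting a bespoke extended region for the MHC (chr6:25.5-34 Mb),
merging overlapping (or abutting) regions, and indexing each merged locus by
its minimum-p variant. Fine-mapping uses Wakefield's approximate Bayes
factor under a single-causal-variant assumption with prior effect variance W
(default 0.15^2) to form 95% credible sets per LD block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import ols_scan, ols_single

__all__ = [
    "QCThresholds",
    "FinemapParams",
    "hwe_exact_test",
    "variant_qc",
    "gwas_linear",
    "define_loci",
    "flag_artifact_signals",
    "abf_finemap",
    "conditional_scan",
    "prioritize_genes",
    "HLA_REGION",
]

HLA_REGION = ("chr6", 25_500_000, 34_000_000)


@dataclass(frozen=True)
class QCThresholds:
    """Variant-QC thresholds.

    ``max_missingness`` is interpreted as a 99% call-rate requirement
    (exclude missingness > 1%). The HWE rule excludes variants with exact-test
    p below ``hwe_p_min`` -- the conventional direction for an equilibrium
    filter.
    """

    max_missingness: float = 0.01
    min_info: float = 0.7
    hwe_p_min: float = 1e-5


@dataclass(frozen=True)
class FinemapParams:
    W: float = 0.0225  # prior effect variance, (0.15 SD)^2
    level: float = 0.95

    def __post_init__(self):
        if self.W <= 0:
            raise ValueError("prior variance W must be positive")
        if not 0 < self.level < 1:
            raise ValueError("credible level must lie in (0,1)")


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, probability mass).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (the standard exact SNP-HWE formulation).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_AA + n_AB  # minor-allele copies determined below
    n_b = 2 * n_BB + n_AB
    rare = min(n_a, n_b)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log-probability of each het count given allele counts (hypergeometric-like)
    from scipy.special import gammaln

    n_rare_hom = (rare - hets) // 2
    n_comm_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_comm_hom + 1)
        + hets * np.log(2)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_AB)
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def variant_qc(
    annotations: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Apply missingness / imputation-INFO / HWE filters; record reasons.

    Expects columns ``missingness``, ``info`` and either ``hwe_p`` or genotype
    counts (``n_AA``, ``n_AB``, ``n_BB``) from which the exact test is run.
    """
    th = thresholds or QCThresholds()
    ann = annotations.copy()
    if "hwe_p" not in ann:
        if {"n_AA", "n_AB", "n_BB"}.issubset(ann.columns):
            ann["hwe_p"] = [
                hwe_exact_test(a, b, c)
                for a, b, c in zip(ann["n_AA"], ann["n_AB"], ann["n_BB"])
            ]
        else:
            ann["hwe_p"] = 1.0
    reason = np.array([""] * len(ann), dtype=object)
    miss = ann["missingness"].to_numpy(dtype=float) > th.max_missingness
    reason[miss] = "missingness"
    info = ann["info"].to_numpy(dtype=float) < th.min_info
    reason[(reason == "") & info] = "info"
    hwe = ann["hwe_p"].to_numpy(dtype=float) < th.hwe_p_min
    reason[(reason == "") & hwe] = "hwe"
    ann["keep"] = reason == ""
    ann["qc_reason"] = reason
    return ann


def gwas_linear(
    phenotype,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of the phenotype on dosage plus covariates.

    Returns one row per variant (id, beta, se, p, n, skipped/reason); betas
    are in phenotype units (SD units for INT phenotypes) with 95% CI bounds
    beta +/- 1.96 se. Constant or covariate-collinear dosages are skipped
    with a reason rather than dropped silently.
    """
    y = np.asarray(phenotype, dtype=float)
    res = ols_scan(y, dosages.to_numpy(dtype=float), covariates)
    res.insert(0, "id", list(dosages.columns))
    res["ci_low"] = res["beta"] - 1.96 * res["se"]
    res["ci_high"] = res["beta"] + 1.96 * res["se"]
    res["reason"] = np.where(res["skipped"], "constant-or-collinear-dosage", "")
    if annotations is not None:
        meta = annotations.reindex(res["id"])
        for col in ("chrom", "pos", "gene", "maf", "mac", "consequence"):
            if col in meta:
                res[col] = meta[col].to_numpy()
    return res


def define_loci(
    results: pd.DataFrame,
    p_threshold: float = 5e-8,
    pad: int = 1_000_000,
    special_regions: tuple = (HLA_REGION,),
) -> pd.DataFrame:
    """Merge significant variants into loci; pick an index variant per locus.

    Significant variants are padded by ``pad`` on each side; a variant inside
    a special region (the MHC by default) contributes the whole region
    instead. Overlapping or abutting half-open regions merge; loci from
    different phenotypes merge too (the ``phenotype`` column, if present, is
    aggregated). The index variant is the minimum-p member, ties broken by
    proximity to the merged-region midpoint, then by smaller coordinate.
    """
    req = {"id", "chrom", "pos", "p"}
    if not req.issubset(results.columns):
        raise ValueError(f"results must carry columns {sorted(req)}")
    sig = results[results["p"] < p_threshold].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "index_variant", "p_index", "n_members",
                     "members", "phenotypes"]
        )
    starts = np.maximum(sig["pos"].to_numpy() - pad, 0)
    ends = sig["pos"].to_numpy() + pad
    for chrom, lo, hi in special_regions:
        inside = (
            (sig["chrom"] == chrom) & (sig["pos"] >= lo) & (sig["pos"] < hi)
        ).to_numpy()
        starts[inside], ends[inside] = lo, hi
    sig["rstart"], sig["rend"] = starts, ends

    loci = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values(["rstart", "rend"]).reset_index(drop=True)
        cur_s, cur_e, members = None, None, []
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, members = row.rstart, row.rend, [row]
            elif row.rstart <= cur_e:  # abutting counts as overlap
                cur_e = max(cur_e, row.rend)
                members.append(row)
            else:
                loci.append((chrom, cur_s, cur_e, members))
                cur_s, cur_e, members = row.rstart, row.rend, [row]
        loci.append((chrom, cur_s, cur_e, members))

    rows = []
    for chrom, s, e, members in loci:
        mid = (s + e) / 2
        best = sorted(
            members, key=lambda m: (m.p, abs(m.pos - mid), m.pos)
        )[0]
        phenos = sorted(
            {getattr(m, "phenotype") for m in members if hasattr(m, "phenotype")}
        )
        rows.append(
            {
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "index_variant": best.id,
                "p_index": best.p,
                "n_members": len(members),
                "members": [m.id for m in members],
                "phenotypes": phenos,
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def flag_artifact_signals(
    pc1_results: pd.DataFrame,
    pc2_results: pd.DataFrame,
    p_threshold: float = 5e-8,
    pc2_threshold: float | None = None,
) -> pd.DataFrame:
    """Label PC1-significant signals clean vs flagged by their PC2 status.

    A signal significant on the shared axis (PC1) but also significant on the
    discordance axis (PC2) is ``flagged`` as artifact-prone; PC1-significant,
    PC2-quiet signals are ``clean``. Use 5e-8 for GWAS mode and 1e-8 for the
    rare-variant report.
    """
    pc2_threshold = p_threshold if pc2_threshold is None else pc2_threshold
    merged = pc1_results[["id", "p"]].merge(
        pc2_results[["id", "p"]], on="id", suffixes=("_pc1", "_pc2"), how="left"
    )
    merged["significant_pc1"] = merged["p_pc1"] <= p_threshold
    merged["flagged"] = merged["significant_pc1"] & (merged["p_pc2"] <= pc2_threshold)
    merged["status"] = np.select(
        [merged["significant_pc1"] & ~merged["flagged"], merged["flagged"]],
        ["clean", "flagged"],
        default="not-significant",
    )
    return merged


def wakefield_abf(beta, se, W: float) -> np.ndarray:
    """Approximate Bayes factor for H1 (effect ~ N(0, W)) vs H0 per variant.

    ABF = sqrt(1 - r) * exp(z^2 r / 2), with r = W / (V + W), z = beta/se,
    V = se^2. Computed in logs for stability.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    V = se**2
    r = W / (V + W)
    z = beta / se
    log_abf = 0.5 * np.log1p(-r) + z**2 * r / 2.0
    return log_abf


def abf_finemap(
    block_results: pd.DataFrame,
    params: FinemapParams | None = None,
) -> pd.DataFrame:
    """Posterior probabilities and the credible set for one LD block.

    Under a single-causal-variant assumption with a flat prior over which
    variant is causal, PP_i = ABF_i / sum_j ABF_j. The credible set is the
    smallest prefix of variants, in descending PP, whose cumulative mass
    reaches the level. Variants lacking a standard error are dropped with a
    warning column rather than silently.
    """
    params = params or FinemapParams()
    res = block_results.copy()
    ok = np.isfinite(res["se"].to_numpy(dtype=float)) & (res["se"].to_numpy(dtype=float) > 0)
    dropped = res[~ok]
    if len(dropped):
        import warnings

        warnings.warn(f"dropping {len(dropped)} variant(s) without usable se")
    res = res[ok].copy()
    log_abf = wakefield_abf(res["beta"].to_numpy(), res["se"].to_numpy(), params.W)
    log_abf -= log_abf.max()
    abf = np.exp(log_abf)
    res["pp"] = abf / abf.sum()
    res = res.sort_values("pp", ascending=False).reset_index(drop=True)
    cum = res["pp"].cumsum()
    cutoff = int(np.searchsorted(cum.to_numpy(), params.level) + 1)
    res["cum_pp"] = cum
    res["in_credible_set"] = np.arange(len(res)) < cutoff
    return res


def conditional_scan(
    phenotype,
    target_dosage,
    conditioning_dosages: pd.DataFrame | None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Association of the target variant conditional on nearby signals.

    The conditioning dosages join the covariates; with an empty conditioning
    set this reduces to the marginal model. Passing the target itself as a
    conditioning variant is an error.
    """
    g = np.asarray(target_dosage, dtype=float)
    if conditioning_dosages is not None and len(conditioning_dosages.columns):
        C = conditioning_dosages.to_numpy(dtype=float)
        if any(np.array_equal(g, C[:, j]) for j in range(C.shape[1])):
            raise ValueError("target variant duplicated in the conditioning set")
        cond = conditioning_dosages.reset_index(drop=True)
        if covariates is not None:
            cov = pd.concat([covariates.reset_index(drop=True), cond], axis=1)
        else:
            cov = cond
    else:
        cov = covariates
    return ols_single(phenotype, g, cov)


def prioritize_genes(
    evidence_matrix: pd.DataFrame,
    gene_locus_map: pd.Series | dict,
) -> pd.DataFrame:
    """Equal-weight evidence sum per gene; pick the top-scoring gene per locus.

    ``evidence_matrix`` is genes x categories with binary entries; the score
    is the row sum. A locus counts as single-gene-prioritized only when a
    unique gene attains the maximal score and that score is positive.
    """
    scores = evidence_matrix.sum(axis=1)
    mapping = pd.Series(gene_locus_map)
    rows = []
    for locus, genes in mapping.groupby(mapping).groups.items():
        s = scores.reindex(genes).fillna(0)
        top = s.max()
        winners = sorted(s.index[s == top]) if top > 0 else []
        rows.append(
            {
                "locus": locus,
                "score": float(top),
                "prioritized_genes": winners,
                "single_gene_prioritized": len(winners) == 1,
            }
        )
    return pd.DataFrame(rows)
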