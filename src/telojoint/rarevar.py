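"""Variant-level ExWAS and gene-level qualifying-variant collapsing analysis.

Rare variation is tested two ways. The ExWAS tests each variant under three
genetic codings (genotypic 0/1/2, dominant 0/1/1, recessive 0/0/1) and
reports, for the rare stratum (MAF below 0.1% by default, carrier floor 5),
the most significant model per variant subject to the shared-axis rule:
significant on PC1 and not on PC2 at 1e-8. The collapsing analysis
aggregates qualifying variants (QVs) per gene into a 0/1 carrier indicator
regressed on the phenotype with the same covariates; ten named QV models,
including a synonymous empirical-control model, define which variants
qualify. Leave-one-out refits quantify single-variant leverage on a gene
signal; lambda_GC summarizes calibration; inverse-variance and Stouffer
meta-analysis combine ancestry strata.

The ten QV model presets follow the naming conventions of published
collapsing-analysis frameworks (ptv, ptvraredmg, flexdmg, ...); the exact
proprietary thresholds are not public, so each preset's predicates are
documented, configurable defaults rather than claimed replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .utils import ols_scan

__all__ = [
    "QVModelSpec",
    "QV_PRESETS",
    "encode_genetic_model",
    "exwas",
    "qv_select",
    "collapsing_test",
    "loo_analysis",
    "lambda_gc",
    "ivw_meta",
    "stouffer_meta",
    "load_qv_models",
]

GENETIC_MODELS = ("genotypic", "dominant", "recessive")
_NULL_MEDIAN_CHI2 = 0.4549364  # median of chi-square(1)
CONSEQUENCES = frozenset({"ptv", "missense", "synonymous", "other"})


@dataclass(frozen=True)
class QVModelSpec:
    """Predicates defining which variants qualify for a collapsing model."""

    name: str
    consequences: frozenset[str]
    max_maf: float = 0.001
    min_revel: float | None = None
    max_mtr_percentile: float | None = None
    min_carriers: int = 5

    def __post_init__(self):
        unknown = self.consequences - CONSEQUENCES
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
        if self.name == "syn" and self.consequences != frozenset({"synonymous"}):
            raise ValueError("the synonymous control admits only synonymous variants")


def _preset(name, cons, **kw) -> QVModelSpec:
    return QVModelSpec(name=name, consequences=frozenset(cons), **kw)


QV_PRESETS: dict[str, QVModelSpec] = {
    s.name: s
    for s in [
        _preset("ptv", {"ptv"}, max_maf=0.001),
        _preset("ptv5pcnt", {"ptv"}, max_maf=0.05),
        _preset("UR", {"ptv", "missense"}, max_maf=5e-5),
        _preset("URmtr", {"ptv", "missense"}, max_maf=5e-5, max_mtr_percentile=50),
        _preset("raredmg", {"missense"}, max_maf=0.001, min_revel=0.5),
        _preset("raredmgmtr", {"missense"}, max_maf=0.001, min_revel=0.5,
                max_mtr_percentile=50),
        _preset("ptvraredmg", {"ptv", "missense"}, max_maf=0.001, min_revel=0.5),
        _preset("flexdmg", {"ptv", "missense"}, max_maf=0.005, min_revel=0.25),
        _preset("flexnonsynmtr", {"ptv", "missense"}, max_maf=0.005,
                max_mtr_percentile=50),
        _preset("syn", {"synonymous"}, max_maf=0.001),
    ]
}


def load_qv_models(path) -> dict[str, QVModelSpec]:
    """Read QV model specs from a YAML mapping name -> predicate fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        out[name] = QVModelSpec(
            name=name,
            consequences=frozenset(spec["consequences"]),
            max_maf=float(spec.get("max_maf", 0.001)),
            min_revel=spec.get("min_revel"),
            max_mtr_percentile=spec.get("max_mtr_percentile"),
            min_carriers=int(spec.get("min_carriers", 5)),
        )
    return out


def encode_genetic_model(dosage, model: str) -> np.ndarray:
    """Recode a 0/1/2 dosage under a genetic model; missing (NaN) propagates."""
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; expected {GENETIC_MODELS}")
    g = np.asarray(dosage, dtype=float)
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("dosages must be 0, 1, 2 or missing")
    if model == "genotypic":
        return g.copy()
    if model == "dominant":
        return np.where(np.isnan(g), np.nan, (g > 0).astype(float))
    return np.where(np.isnan(g), np.nan, (g == 2).astype(float))


def exwas(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    annotations: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    max_maf: float = 0.001,
    min_carriers: int = 5,
    p_threshold: float = 1e-8,
    models: tuple[str, ...] = GENETIC_MODELS,
) -> dict:
    """Variant-level scan under the three genetic codings plus the rare report.

    ``phenotypes`` must contain ``pc1`` and ``pc2`` columns (additional
    columns, e.g. the single metrics, are scanned too). Returns the full
    per-variant x model x phenotype results and the filtered report: rare
    variants (MAF < ``max_maf``), best (most significant PC1) model per
    variant with at least ``min_carriers`` carriers under that coding,
    keeping variants with PC1 p <= threshold and PC2 p > threshold.
    """
    if not {"pc1", "pc2"}.issubset(phenotypes.columns):
        raise ValueError("phenotypes must include pc1 and pc2")
    frames = []
    for model in models:
        coded = pd.DataFrame(
            {vid: encode_genetic_model(genotypes[vid], model) for vid in genotypes},
        )
        carriers = (coded > 0).sum(axis=0)
        for pheno in phenotypes.columns:
            res = ols_scan(
                phenotypes[pheno].to_numpy(dtype=float),
                coded.to_numpy(dtype=float),
                covariates,
            )
            res.insert(0, "id", list(coded.columns))
            res.insert(1, "model", model)
            res.insert(2, "phenotype", pheno)
            res["carriers"] = carriers.to_numpy()
            frames.append(res)
    results = pd.concat(frames, ignore_index=True)
    results["ci_low"] = results["beta"] - 1.96 * results["se"]
    results["ci_high"] = results["beta"] + 1.96 * results["se"]

    maf = annotations["maf_obs"] if "maf_obs" in annotations else annotations["maf"]
    rare_ids = set(annotations.index[maf < max_maf])
    usable = results[
        results["id"].isin(rare_ids)
        & (results["carriers"] >= min_carriers)
        & ~results["skipped"]
    ]
    pc1 = usable[usable["phenotype"] == "pc1"]
    best = pc1.sort_values("p").drop_duplicates("id", keep="first")
    pc2 = usable[usable["phenotype"] == "pc2"].set_index(["id", "model"])["p"]
    report_rows = []
    for row in best.itertuples(index=False):
        p2 = pc2.get((row.id, row.model), np.nan)
        if row.p <= p_threshold and not (p2 <= p_threshold):
            report_rows.append({**row._asdict(), "p_pc2": p2})
    report = pd.DataFrame(report_rows)
    return {"results": results, "report": report, "best_pc1": best}


def qv_select(annotations: pd.DataFrame, spec: QVModelSpec) -> dict[str, list[str]]:
    """Qualifying variant ids per gene under one QV model's predicates."""
    unknown = set(annotations["consequence"]) - CONSEQUENCES
    if unknown:
        raise ValueError(f"unknown consequence labels: {sorted(unknown)}")
    maf = annotations["maf_obs"] if "maf_obs" in annotations else annotations["maf"]
    keep = annotations["consequence"].isin(spec.consequences) & (maf <= spec.max_maf)
    if spec.min_revel is not None:
        revel = annotations["revel"].fillna(np.inf)  # PTVs have no REVEL; always pass
        is_missense = annotations["consequence"] == "missense"
        keep &= ~is_missense | (revel >= spec.min_revel)
    if spec.max_mtr_percentile is not None:
        mtr = annotations["mtr_percentile"].fillna(0.0)
        keep &= mtr <= spec.max_mtr_percentile
    out: dict[str, list[str]] = {}
    for gene, grp in annotations[keep].groupby("gene"):
        out[gene] = list(grp.index)
    return out


def _carrier_indicator(genotypes: pd.DataFrame, variant_ids: list[str]) -> np.ndarray:
    return (genotypes[variant_ids].to_numpy(dtype=float) > 0).any(axis=1).astype(float)


def collapsing_test(
    phenotype,
    genotypes: pd.DataFrame,
    qv_by_gene: dict[str, list[str]],
    covariates: pd.DataFrame | None = None,
    min_carriers: int = 5,
    model_name: str = "",
) -> pd.DataFrame:
    """Gene-level burden test: phenotype ~ carrier indicator + covariates.

    A sample is a carrier when it holds at least one qualifying allele in the
    gene. Genes below the carrier floor are skipped with a reason.
    """
    y = np.asarray(phenotype, dtype=float)
    genes = sorted(qv_by_gene)
    carrier_cols = {}
    rows_skipped = []
    for gene in genes:
        ind = _carrier_indicator(genotypes, qv_by_gene[gene])
        c = int(ind.sum())
        if c == 0:
            rows_skipped.append((gene, c, "zero-carriers"))
        elif c < min_carriers:
            rows_skipped.append((gene, c, "below-carrier-floor"))
        else:
            carrier_cols[gene] = ind
    if carrier_cols:
        mat = np.column_stack(list(carrier_cols.values()))
        res = ols_scan(y, mat, covariates)
        res.insert(0, "gene", list(carrier_cols))
        res["carriers"] = mat.sum(axis=0).astype(int)
    else:
        res = pd.DataFrame(columns=["gene", "beta", "se", "p", "n", "skipped", "carriers"])
    res["qv_model"] = model_name
    res["ci_low"] = res["beta"] - 1.96 * res["se"]
    res["ci_high"] = res["beta"] + 1.96 * res["se"]
    res["reason"] = ""
    if rows_skipped:
        res = pd.concat(
            [
                res,
                pd.DataFrame(
                    [
                        {"gene": g, "carriers": c, "reason": r, "qv_model": model_name}
                        for g, c, r in rows_skipped
                    ]
                ),
            ],
            ignore_index=True,
        )
    return res


def loo_analysis(
    phenotype,
    genotypes: pd.DataFrame,
    gene: str,
    variant_ids: list[str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Leave-one-variant-out refits of a gene's collapsing signal.

    Excluding a variant that drives the signal inflates the refit p-value;
    the table reports the excluded variant and the resulting p. Single-QV
    genes get an explicit not-applicable row.
    """
    if len(variant_ids) < 2:
        return pd.DataFrame(
            [{"gene": gene, "excluded_variant": None, "p": np.nan,
              "applicable": False}]
        )
    y = np.asarray(phenotype, dtype=float)
    mats = []
    for vid in variant_ids:
        remaining = [v for v in variant_ids if v != vid]
        mats.append(_carrier_indicator(genotypes, remaining))
    res = ols_scan(y, np.column_stack(mats), covariates)
    out = pd.DataFrame(
        {
            "gene": gene,
            "excluded_variant": variant_ids,
            "beta": res["beta"].to_numpy(),
            "se": res["se"].to_numpy(),
            "p": res["p"].to_numpy(),
            "applicable": True,
        }
    )
    return out


def lambda_gc(p_values) -> float:
    """Genomic-control inflation: median association chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _NULL_MEDIAN_CHI2)


def ivw_meta(betas, ses) -> dict:
    """Fixed-effect inverse-variance-weighted meta-analysis."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0 or b.shape != s.shape:
        raise ValueError("need aligned, non-empty beta and se vectors")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((b * w).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    return {"beta": beta, "se": se, "z": z, "p": float(2 * stats.norm.sf(abs(z)))}


def stouffer_meta(z_scores, sample_sizes) -> dict:
    """Stouffer's method with sqrt(n) weights."""
    z = np.asarray(z_scores, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if z.shape != n.shape or z.size == 0:
        raise ValueError("need aligned, non-empty z and n vectors")
    Z = float((np.sqrt(n) * z).sum() / np.sqrt(n.sum()))
    return {"z": Z, "p": float(2 * stats.norm.sf(abs(Z)))}
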