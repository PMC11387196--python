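"""Clonal hematopoiesis (CH) call filtering, VAF strata and TL association.

Somatic driver calls are filtered to 0.03 <= VAF <= 0.4 with allelic depth
>= 3; samples with a prior hematological malignancy or a lymphocyte count
above 5e9 cells/L are excluded from association. Carrier status per driver
gene (and "Any" across the panel) is tested against the telomere phenotype
with age, sex, age^2, ancestry PCs 1-4 and smoking covariates. Clone size is
handled by a partition of the VAF range into four strata (3-5%, >5-10%,
>10-20%, >20%); the ordinal trend model recodes carrier status as the
stratum index (0 for non-carriers) so the fitted slope's sign is the
direction of TL change with clone size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import ols_single

__all__ = [
    "CHParams",
    "DEFAULT_CH_GENES",
    "exclusion_filter",
    "filter_ch_calls",
    "vaf_stratify",
    "ch_association",
    "ch_vaf_trend",
]

# A 15-gene default panel of established CH / myeloid drivers.
DEFAULT_CH_GENES = (
    "DNMT3A", "TET2", "ASXL1", "PPM1D", "SRSF2", "SF3B1", "JAK2", "TP53",
    "CBL", "GNB1", "IDH2", "CALR", "MPL", "U2AF1", "PRPF8",
)

STRATUM_LABELS = ("3-5%", ">5-10%", ">10-20%", ">20%")


@dataclass(frozen=True)
class CHParams:
    vaf_min: float = 0.03
    vaf_max: float = 0.40
    ad_min: int = 3
    # upper bounds of the four VAF strata partitioning [vaf_min, vaf_max]
    strata_upper: tuple[float, ...] = (0.05, 0.10, 0.20, 0.40)
    lymphocyte_ceiling: float = 5.0  # 1e9 cells per liter
    genes: tuple[str, ...] = field(default=DEFAULT_CH_GENES)

    def __post_init__(self):
        if not self.strata_upper or self.strata_upper[-1] != self.vaf_max:
            raise ValueError("strata must partition [vaf_min, vaf_max]")


def exclusion_filter(cohort: pd.DataFrame, params: CHParams | None = None) -> pd.DataFrame:
    """Flag samples excluded for malignancy or high lymphocyte count.

    Returns (sample_id, keep, reason); shared precondition for the
    rare-variant and CH association stages.
    """
    params = params or CHParams()
    reason = np.array([""] * len(cohort), dtype=object)
    mal = cohort["heme_malignancy"].to_numpy(dtype=bool)
    reason[mal] = "hematological-malignancy"
    lymph = cohort["lymphocyte_count"].to_numpy(dtype=float) > params.lymphocyte_ceiling
    reason[(reason == "") & lymph] = "lymphocyte-count"
    return pd.DataFrame(
        {"sample_id": cohort["sample_id"], "keep": reason == "", "reason": reason}
    )


def filter_ch_calls(calls: pd.DataFrame, params: CHParams | None = None) -> pd.DataFrame:
    """Retain calls with vaf_min <= VAF <= vaf_max (closed) and AD >= ad_min."""
    params = params or CHParams()
    vaf = calls["vaf"].to_numpy(dtype=float)
    if np.any((vaf <= 0) | (vaf >= 1)):
        raise ValueError("VAF must lie strictly inside (0, 1)")
    keep = (vaf >= params.vaf_min) & (vaf <= params.vaf_max)
    keep &= calls["ad"].to_numpy(dtype=float) >= params.ad_min
    return calls[keep].reset_index(drop=True)


def vaf_stratify(
    calls: pd.DataFrame, params: CHParams | None = None
) -> pd.DataFrame:
    """Per sample x gene: maximal VAF, stratum label and index.

    Multiple calls in the same gene collapse to the maximum VAF (clone-size
    proxy). Strata are (vaf_min-u1], (u1-u2], ... with closed upper bounds,
    matching labels 3-5%, >5-10%, >10-20%, >20%. Stratum index runs 1..4;
    non-carriers are index 0 by convention in the trend model.
    """
    params = params or CHParams()
    if calls.empty:
        return pd.DataFrame(columns=["sample_id", "gene", "vaf", "stratum", "stratum_index"])
    agg = (
        calls.groupby(["sample_id", "gene"], as_index=False)["vaf"].max()
    )
    uppers = np.asarray(params.strata_upper)
    idx = np.searchsorted(uppers, agg["vaf"].to_numpy(dtype=float), side="left")
    idx = np.clip(idx, 0, len(uppers) - 1)
    agg["stratum"] = [STRATUM_LABELS[i] for i in idx]
    agg["stratum_index"] = idx + 1
    return agg


def _carrier_frame(
    cohort: pd.DataFrame, stratified: pd.DataFrame, genes: tuple[str, ...]
) -> pd.DataFrame:
    """Samples x (genes + Any) carrier stratum index (0 = non-carrier)."""
    out = pd.DataFrame(0, index=cohort["sample_id"], columns=list(genes) + ["Any"])
    if not stratified.empty:
        for row in stratified.itertuples(index=False):
            if row.gene in out.columns and row.sample_id in out.index:
                out.loc[row.sample_id, row.gene] = row.stratum_index
        panel = out[list(genes)].max(axis=1)
        out["Any"] = panel
    return out


def ch_association(
    phenotype,
    cohort: pd.DataFrame,
    stratified: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    params: CHParams | None = None,
) -> pd.DataFrame:
    """Carrier (any qualifying clone) vs phenotype, per gene and overall."""
    params = params or CHParams()
    y = np.asarray(phenotype, dtype=float)
    strata = _carrier_frame(cohort, stratified, params.genes)
    rows = []
    for gene in list(params.genes) + ["Any"]:
        carrier = (strata[gene].to_numpy() > 0).astype(float)
        n_car = int(carrier.sum())
        if n_car == 0:
            rows.append({"gene": gene, "carriers": 0, "skipped": True, "reason": "zero-carriers"})
            continue
        res = ols_single(y, carrier, covariates)
        rows.append(
            {"gene": gene, "carriers": n_car, "beta": res["beta"], "se": res["se"],
             "p": res["p"], "ci_low": res["beta"] - 1.96 * res["se"],
             "ci_high": res["beta"] + 1.96 * res["se"], "skipped": False, "reason": ""}
        )
    return pd.DataFrame(rows)


def ch_vaf_trend(
    phenotype,
    cohort: pd.DataFrame,
    stratified: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    params: CHParams | None = None,
) -> pd.DataFrame:
    """Ordinal VAF-stratum trend per gene: phenotype ~ stratum index (0..4).

    The slope sign is the direction of telomere-length change with clone
    size. Genes whose carriers occupy fewer than two strata have no
    estimable within-carrier trend and are flagged.
    """
    params = params or CHParams()
    y = np.asarray(phenotype, dtype=float)
    strata = _carrier_frame(cohort, stratified, params.genes)
    rows = []
    for gene in list(params.genes) + ["Any"]:
        code = strata[gene].to_numpy(dtype=float)
        occupied = np.unique(code[code > 0])
        if occupied.size < 2:
            rows.append(
                {"gene": gene, "carriers": int((code > 0).sum()), "estimable": False,
                 "reason": "carriers-in-fewer-than-two-strata"}
            )
            continue
        res = ols_single(y, code, covariates)
        rows.append(
            {"gene": gene, "carriers": int((code > 0).sum()), "beta": res["beta"],
             "se": res["se"], "p": res["p"], "estimable": True, "reason": ""}
        )
    return pd.DataFrame(rows)
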