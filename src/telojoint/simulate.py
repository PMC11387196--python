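"""Synthetic cohorts with the statistical structure the telomere pipeline assumes.

The generator emulates a latent per-individual telomere length (TL, standardized
to SD units) measured by two noisy instruments:

* a qPCR T:S ratio whose only systematic bias is a reference-gene artifact
  variant (an analog of the HBB-linked qPCR signal) that shifts the qPCR
  reading of carriers without touching true TL, and
* a WGS TelSeq estimate contaminated by latent sequencing "technical factors"
  that also imprint genome-wide coverage structure, so that coverage-PCA
  residualization can remove them.

Planted genetic truth includes common variants, a rare allelic series with
opposing effect signs in one gene, a gene-level burden signal, a
driver-plus-passengers gene for leave-one-out analysis, a rare LD-contamination
pair, and clonal-hematopoiesis (CH) driver genes whose acquisition probability
depends on age and on TL and whose clones shift measured TL as a function of
clone size (VAF). Everything is returned together with a truth table so that
downstream operations can be tested as parameter-recovery problems.

All randomness flows from a single ``numpy`` Generator seeded by the config;
the same config and seed reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "CHGeneSpec",
    "VariantDef",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_ch",
]

# Rough GRCh38 anchors for the analog genes used by the default configuration.
GENE_MAP = {
    "ACD": ("chr16", 67_659_000),
    "CTC1": ("chr17", 8_237_000),
    "POT1": ("chr7", 124_822_000),
    "SAMHD1": ("chr20", 36_898_000),
    "SOGA1": ("chr20", 36_810_000),
    "HBB": ("chr11", 5_225_000),
    "TERT": ("chr5", 1_253_000),
    "RTEL1": ("chr20", 63_657_000),
    "DNMT3A": ("chr2", 25_234_000),
    "TET2": ("chr4", 105_233_000),
    "SRSF2": ("chr17", 76_734_000),
    "PPM1D": ("chr17", 60_600_000),
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantDef:
    """Specification of one simulated variant."""

    gene: str
    maf: float
    effect: float = 0.0  # additive effect per alt allele, SD units of latent TL
    consequence: str = "missense"
    chrom: str | None = None
    pos: int | None = None
    qpcr_only: bool = False  # artifact: shifts the qPCR reading, not latent TL
    ld_with: str | None = None  # id of an earlier variant to correlate with
    ld_r: float = 0.0
    revel: float | None = None
    mtr_percentile: float | None = None
    ensure_carrier: bool = False  # redraw until >=1 carrier (planted signals)

    @property
    def vid(self) -> str:
        return f"{self.chrom}-{self.pos}-A-G"


@dataclass(frozen=True)
class CHGeneSpec:
    """One CH driver gene: acquisition model and clone-size TL effect.

    ``tl_to_acquisition`` plants the "cause" direction (TL modulating clone
    acquisition); ``vaf_to_tl`` plants the "effect" direction (the clone
    shifting measured TL in proportion to its VAF). They are independent so
    either direction can be recovered on its own.
    """

    gene: str
    base_prevalence: float
    age_slope: float  # logit units per SD of age
    vaf_alpha: float = 2.0
    vaf_beta: float = 5.0
    tl_to_acquisition: float = 0.0  # logit units per SD of latent TL
    vaf_to_tl: float = 0.0  # SD units of TL per unit VAF


def _default_allelic_series() -> list[tuple[str, float, float]]:
    # Four rare missense variants in one gene, two lengthening and two
    # shortening, patterned on a reported allelic series; effects are tripled
    # relative to the biobank-scale report so the signals are detectable at
    # the 20,000-sample desk scale.
    return [
        ("ACD", 1.6e-4, 2.55),
        ("ACD", 3.8e-4, 2.49),
        ("ACD", 6.4e-4, -0.90),
        ("ACD", 7.1e-4, -1.41),
    ]


def _default_burden() -> list[tuple[str, float, float]]:
    return [("CTC1", 0.01, 0.7)]


def _default_loo_gene() -> tuple[str, list[tuple[float, float]]]:
    # One true driver plus four null passengers, all PTVs in the same gene:
    # leave-one-out should single out the driver.
    return ("POT1", [(5e-4, 1.5), (1e-4, 0.0), (1e-4, 0.0), (1e-4, 0.0), (1e-4, 0.0)])


def _default_ld_pair() -> tuple[str, float, float, str, float]:
    # (causal gene, causal MAF, causal effect, shadow gene, target LD r)
    return ("SAMHD1", 8e-4, 1.5, "SOGA1", 0.99)


def _default_ch_specs() -> list[CHGeneSpec]:
    return [
        CHGeneSpec("DNMT3A", 0.03, 0.5, tl_to_acquisition=0.4, vaf_to_tl=0.0),
        CHGeneSpec("TET2", 0.015, 0.6, tl_to_acquisition=0.0, vaf_to_tl=-2.0),
        CHGeneSpec("SRSF2", 0.01, 0.8, tl_to_acquisition=-0.3, vaf_to_tl=3.0),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 20_000
    seed: int = 2024
    age_range: tuple[float, float] = (40.0, 70.0)
    n_common_variants: int = 50
    n_rare_variants: int = 60  # null rare background, 3 per null gene
    common_effect_sd: float = 0.05
    allelic_series_spec: list[tuple[str, float, float]] = field(
        default_factory=_default_allelic_series
    )
    burden_gene_spec: list[tuple[str, float, float]] = field(default_factory=_default_burden)
    loo_gene_spec: tuple[str, list[tuple[float, float]]] | None = field(
        default_factory=_default_loo_gene
    )
    ld_pair_spec: tuple[str, float, float, str, float] | None = field(
        default_factory=_default_ld_pair
    )
    artifact_variant: tuple[float, float] | None = (0.10, -0.5)  # (MAF, qPCR-only effect)
    n_tiles: int = 500
    n_tech_factors: int = 3
    tech_loading_sd: float = 1.0  # depth units per tech-factor unit, per tile
    telseq_tech_effect: float = 0.5  # SD units of TL per tech-factor unit
    measurement_noise_sd_qpcr: float = 0.93
    measurement_noise_sd_telseq: float = 0.93
    ch_gene_specs: list[CHGeneSpec] = field(default_factory=_default_ch_specs)
    # covariate effects on latent TL (SD units)
    age_effect: float = -0.30  # per SD of age: telomeres shorten with age
    sex_effect: float = 0.10
    ancestry_effects: tuple[float, ...] = (0.05, -0.03, 0.02, -0.02)
    depth_mean: float = 32.5
    depth_sd: float = 2.0
    tile_noise_sd: float = 1.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for gene, maf, _ in self.allelic_series_spec:
            _check_maf(maf, gene)
        for gene, cf, _ in self.burden_gene_spec:
            if not 0 < cf < 1:
                raise ValueError(f"carrier frequency for {gene} out of (0,1)")
            if cf * self.n_samples < 1:
                raise ValueError(
                    f"burden gene {gene}: carrier frequency x n_samples < 1 carrier"
                )
        planted = [m for _, m, e in self.allelic_series_spec if e != 0]
        if self.loo_gene_spec is not None:
            planted += [m for m, e in self.loo_gene_spec[1] if e != 0]
        if self.ld_pair_spec is not None:
            planted.append(self.ld_pair_spec[1])
        for maf in planted:
            if 2 * maf * self.n_samples < 1:
                raise ValueError(
                    f"planted variant with MAF {maf}: fewer than one expected carrier "
                    f"at n={self.n_samples}"
                )
        if self.artifact_variant is not None:
            _check_maf(self.artifact_variant[0], "artifact variant")


def _check_maf(maf: float, label: str) -> None:
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF for {label} must lie in (0, 0.5], got {maf}")


class CHResult(NamedTuple):
    calls: pd.DataFrame  # sample_id, gene, vaf, ad, dp
    tl_shift: np.ndarray  # per-sample TL shift induced by clones, SD units
    truth: pd.DataFrame  # per-gene planted directions


class SimulatedCohort(NamedTuple):
    cohort: pd.DataFrame
    genotypes: pd.DataFrame  # samples x variants, dosage 0/1/2
    annotations: pd.DataFrame  # per-variant annotation
    coverage: pd.DataFrame  # samples x tiles, mean depth
    measurements: pd.DataFrame  # sample_id, qpcr_raw, telseq_raw
    ch_calls: pd.DataFrame
    truth: "TruthTable"


@dataclass
class TruthTable:
    latent_tl: np.ndarray  # measurement target (includes CH clone shifts)
    latent_tl_germline: np.ndarray  # standardized, pre-CH
    genetic_score: np.ndarray  # total planted genetic contribution
    tech_factors: np.ndarray  # n x k
    variant_effects: pd.DataFrame  # id, gene, true_beta (post-standardization)
    burden_effects: pd.DataFrame  # gene, carrier_freq, true_beta
    ch_truth: pd.DataFrame  # gene, tl_to_acquisition, vaf_to_tl


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n: int,
    variant_spec: Sequence[VariantDef],
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw diploid dosages, binomial(2, MAF) per variant, with optional LD pairs.

    An LD pair is produced by copying the partner's dosages and redrawing a
    fraction ``1 - ld_r`` of samples independently, which realizes a dosage
    correlation of approximately ``ld_r``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages: dict[str, np.ndarray] = {}
    rows = []
    for v in variant_spec:
        _check_maf(v.maf, v.gene)
        if v.chrom is None or v.pos is None:
            raise ValueError(f"variant in {v.gene} lacks coordinates")
        vid = f"{v.chrom.removeprefix('chr')}-{v.pos}-{_BASES[v.pos % 4]}-{_BASES[(v.pos + 1) % 4]}"
        if v.ld_with is not None:
            if v.ld_with not in dosages:
                raise ValueError(f"LD partner {v.ld_with} not yet simulated")
            g = dosages[v.ld_with].copy()
            redraw = rng.random(n) > v.ld_r
            g[redraw] = rng.binomial(2, v.maf, size=int(redraw.sum()))
            if np.array_equal(g, dosages[v.ld_with]):
                # rare variants: the redraw may touch no carrier, leaving the
                # pair identical; break one shared carrier so LD is near-perfect
                # rather than exact duplication
                carriers = np.flatnonzero(g > 0)
                if carriers.size > 1:
                    g[carriers[rng.integers(carriers.size)]] = 0
        else:
            g = rng.binomial(2, v.maf, size=n)
            if v.ensure_carrier:
                tries = 0
                while g.sum() == 0 and tries < 100:
                    g = rng.binomial(2, v.maf, size=n)
                    tries += 1
                if g.sum() == 0:
                    raise ValueError(f"could not realize a carrier for {vid}")
        dosages[vid] = g.astype(np.int8)
        mac = int(min(g.sum(), 2 * n - g.sum()))
        rows.append(
            {
                "id": vid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": _BASES[v.pos % 4],
                "alt": _BASES[(v.pos + 1) % 4],
                "gene": v.gene,
                "consequence": v.consequence,
                "maf": v.maf,
                "maf_obs": g.mean() / 2.0,
                "mac": mac,
                "missingness": 0.0,
                "info": 1.0,
                "revel": v.revel if v.revel is not None else np.nan,
                "mtr_percentile": v.mtr_percentile if v.mtr_percentile is not None else np.nan,
                "true_beta": v.effect,
                "qpcr_only": v.qpcr_only,
            }
        )
    G = pd.DataFrame(dosages)
    ann = pd.DataFrame(rows).set_index("id", drop=False)
    return G, ann


def _default_variant_defs(config: GeneratorConfig, rng: np.random.Generator) -> list[VariantDef]:
    defs: list[VariantDef] = []
    # common background, spread over the autosomes far enough apart that each
    # would form its own GWAS locus
    for i in range(config.n_common_variants):
        chrom = f"chr{1 + i % 22}"
        pos = 10_000_000 + (i // 22) * 40_000_000 + (i % 22) * 1_000_000
        maf = float(rng.uniform(0.05, 0.5))
        beta = float(rng.normal(0.0, config.common_effect_sd))
        defs.append(
            VariantDef("COMMON", maf, beta, consequence="other", chrom=chrom, pos=pos)
        )
    # null rare background, three variants per null gene with mixed consequences
    consequences = ["ptv", "missense", "synonymous"]
    for i in range(config.n_rare_variants):
        gene = f"GENE{i // 3 + 1:03d}"
        chrom = "chr3"
        pos = 20_000_000 + i * 300_000
        maf = float(10 ** rng.uniform(-4, -3))
        cons = consequences[i % 3]
        defs.append(
            VariantDef(
                gene,
                maf,
                0.0,
                consequence=cons,
                chrom=chrom,
                pos=pos,
                revel=float(rng.uniform(0, 1)) if cons == "missense" else None,
                mtr_percentile=float(rng.uniform(0, 100)),
            )
        )
    # allelic series
    for j, (gene, maf, effect) in enumerate(config.allelic_series_spec):
        chrom, base = GENE_MAP.get(gene, ("chr16", 67_659_000))
        defs.append(
            VariantDef(
                gene,
                maf,
                effect,
                consequence="missense",
                chrom=chrom,
                pos=base + 17 * (j + 1),
                revel=0.85,
                mtr_percentile=20.0,
                ensure_carrier=effect != 0,
            )
        )
    # driver + passengers for leave-one-out
    if config.loo_gene_spec is not None:
        gene, variants = config.loo_gene_spec
        chrom, base = GENE_MAP.get(gene, ("chr7", 124_822_000))
        for j, (maf, effect) in enumerate(variants):
            defs.append(
                VariantDef(
                    gene,
                    maf,
                    effect,
                    consequence="ptv",
                    chrom=chrom,
                    pos=base + 23 * (j + 1),
                    mtr_percentile=10.0,
                    ensure_carrier=effect != 0,
                )
            )
    # LD contamination pair
    if config.ld_pair_spec is not None:
        causal_gene, maf, effect, shadow_gene, ld_r = config.ld_pair_spec
        chrom_c, base_c = GENE_MAP.get(causal_gene, ("chr20", 36_898_000))
        chrom_s, base_s = GENE_MAP.get(shadow_gene, ("chr20", 36_810_000))
        causal = VariantDef(
            causal_gene,
            maf,
            effect,
            consequence="missense",
            chrom=chrom_c,
            pos=base_c + 455,
            revel=0.9,
            mtr_percentile=15.0,
            ensure_carrier=True,
        )
        defs.append(causal)
        causal_id = (
            f"{chrom_c.removeprefix('chr')}-{base_c + 455}-"
            f"{_BASES[(base_c + 455) % 4]}-{_BASES[(base_c + 456) % 4]}"
        )
        defs.append(
            VariantDef(
                shadow_gene,
                maf,
                0.0,
                consequence="missense",
                chrom=chrom_s,
                pos=base_s + 11,
                revel=0.4,
                mtr_percentile=60.0,
                ld_with=causal_id,
                ld_r=ld_r,
            )
        )
    # qPCR reference-gene artifact
    if config.artifact_variant is not None:
        maf, effect = config.artifact_variant
        chrom, base = GENE_MAP["HBB"]
        defs.append(
            VariantDef(
                "HBB",
                maf,
                effect,
                consequence="other",
                chrom=chrom,
                pos=base + 812,
                qpcr_only=True,
            )
        )
    return defs


# ---------------------------------------------------------------------------
# clonal hematopoiesis


def simulate_ch(
    cohort: pd.DataFrame,
    latent_tl: np.ndarray,
    ch_gene_specs: Sequence[CHGeneSpec],
    seed: int | np.random.Generator = 0,
    mean_depth: float = 120.0,
) -> CHResult:
    """Simulate somatic CH calls for each driver gene.

    Per gene, carrier probability follows a logistic model in standardized age
    and latent TL; carrier VAF is Beta-distributed and rescaled to (0.01,
    0.45) so that the printed VAF filters have something to remove; allelic
    depth is binomial at an exome-like total depth and the reported VAF is the
    empirical AD/DP. The induced TL shift of a clone is ``vaf_to_tl * VAF``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)
    latent_tl = np.asarray(latent_tl, dtype=float)
    if latent_tl.shape[0] != n:
        raise ValueError("latent TL not aligned to cohort")
    age = cohort["age"].to_numpy(dtype=float)
    z_age = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)

    shift = np.zeros(n)
    rows = []
    truth_rows = []
    for spec in ch_gene_specs:
        base = np.clip(spec.base_prevalence, 1e-12, 1 - 1e-12)
        logit = (
            np.log(base / (1 - base))
            + spec.age_slope * z_age
            + spec.tl_to_acquisition * latent_tl
        )
        p = 1.0 / (1.0 + np.exp(-logit))
        carrier = rng.random(n) < p
        idx = np.flatnonzero(carrier)
        if idx.size:
            raw_vaf = 0.01 + 0.44 * rng.beta(spec.vaf_alpha, spec.vaf_beta, size=idx.size)
            dp = rng.poisson(mean_depth, size=idx.size) + 1
            ad = rng.binomial(dp, raw_vaf)
            keep = ad > 0
            idx, raw_vaf, dp, ad = idx[keep], raw_vaf[keep], dp[keep], ad[keep]
            shift[idx] += spec.vaf_to_tl * raw_vaf
            sample_ids = cohort["sample_id"].to_numpy()[idx]
            for sid, a, d in zip(sample_ids, ad, dp):
                rows.append(
                    {"sample_id": sid, "gene": spec.gene, "vaf": a / d, "ad": int(a), "dp": int(d)}
                )
        truth_rows.append(
            {
                "gene": spec.gene,
                "tl_to_acquisition": spec.tl_to_acquisition,
                "vaf_to_tl": spec.vaf_to_tl,
            }
        )
    calls = pd.DataFrame(rows, columns=["sample_id", "gene", "vaf", "ad", "dp"])
    return CHResult(calls, shift, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: GeneratorConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort, measurements and truth tables."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # --- covariates -------------------------------------------------------
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    ancestry = rng.normal(size=(n, 4))
    site = np.where(rng.random(n) < 0.5, "site_A", "site_B")
    plate = np.array([f"plate_{i:02d}" for i in rng.integers(0, 20, size=n)])
    ever_smoked = rng.random(n) < 0.45
    pack_years = np.where(ever_smoked, rng.lognormal(2.8, 0.7, size=n), 0.0)
    lymph = rng.lognormal(0.55, 0.45, size=n)
    malignancy = rng.random(n) < 0.005
    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "ancestry_pc1": ancestry[:, 0],
            "ancestry_pc2": ancestry[:, 1],
            "ancestry_pc3": ancestry[:, 2],
            "ancestry_pc4": ancestry[:, 3],
            "sequencing_site": site,
            "genotyping_plate": plate,
            "ever_smoked": ever_smoked.astype(int),
            "pack_years": pack_years,
            "lymphocyte_count": lymph,
            "heme_malignancy": malignancy.astype(int),
            "batch": 0,
        }
    )

    # --- genotypes --------------------------------------------------------
    defs = _default_variant_defs(config, rng)
    genotypes, annotations = simulate_genotypes(n, defs, rng)

    # --- latent telomere length ------------------------------------------
    z_age = (age - age.mean()) / age.std()
    fixed = (
        config.age_effect * z_age
        + config.sex_effect * (sex - 0.5)
        + ancestry[:, : len(config.ancestry_effects)] @ np.asarray(config.ancestry_effects)
    )
    betas = annotations["true_beta"].to_numpy()
    germline = ~annotations["qpcr_only"].to_numpy()
    G = genotypes.to_numpy(dtype=float)
    centered = G - 2 * annotations["maf"].to_numpy()
    genetic = centered @ (betas * germline)

    burden_carrier = {}
    for gene, carrier_freq, effect in config.burden_gene_spec:
        # spread the carrier frequency over several PTVs so the gene has a
        # realistic qualifying-variant structure; per-variant MAF stays well
        # below the rare QV ceiling so observed-MAF sampling noise cannot
        # push qualifying variants out of their own model
        n_vars = 10
        per_maf = carrier_freq / (2 * n_vars)
        chrom, base = GENE_MAP.get(gene, ("chr17", 8_237_000))
        bdefs = [
            VariantDef(
                gene,
                per_maf,
                0.0,
                consequence="ptv",
                chrom=chrom,
                pos=base + 31 * (j + 1),
                mtr_percentile=5.0,
                ensure_carrier=True,
            )
            for j in range(n_vars)
        ]
        bG, bann = simulate_genotypes(n, bdefs, rng)
        carrier = (bG.to_numpy() > 0).any(axis=1)
        genetic = genetic + effect * (carrier - carrier.mean())
        genotypes = pd.concat([genotypes, bG], axis=1)
        annotations = pd.concat([annotations, bann])
        burden_carrier[gene] = (carrier_freq, effect)

    # residual variance chosen so the composed latent trait has variance ~1
    expl = float(np.var(fixed) + np.var(genetic))
    resid_sd = np.sqrt(max(1.0 - expl, 0.05))
    latent_pre = fixed + genetic + resid_sd * rng.normal(size=n)
    scale = latent_pre.std()
    latent_pre = (latent_pre - latent_pre.mean()) / scale
    # record effects on the standardized scale actually measured downstream
    annotations = annotations.copy()
    annotations["true_beta"] = np.where(
        annotations["qpcr_only"], annotations["true_beta"], annotations["true_beta"] / scale
    )
    genetic_score = genetic / scale

    # --- clonal hematopoiesis --------------------------------------------
    ch = simulate_ch(cohort, latent_pre, config.ch_gene_specs, rng)
    latent = latent_pre + ch.tl_shift

    # --- technical structure and measurements ----------------------------
    k = config.n_tech_factors
    tech = rng.normal(size=(n, k)) if k > 0 else np.zeros((n, 0))
    loadings = (
        rng.normal(0.0, config.tech_loading_sd, size=(config.n_tiles, k))
        if k > 0
        else np.zeros((config.n_tiles, 0))
    )
    depth = rng.normal(config.depth_mean, config.depth_sd, size=n)
    cov = depth[:, None] + tech @ loadings.T
    if config.tile_noise_sd > 0:
        cov = cov + rng.normal(0.0, config.tile_noise_sd, size=(n, config.n_tiles))
    cov = np.maximum(cov, 0.0)
    coverage = pd.DataFrame(
        cov, columns=[f"tile_{j:05d}" for j in range(config.n_tiles)]
    )
    coverage.insert(0, "sample_id", cohort["sample_id"])

    telseq_raw = latent + config.telseq_tech_effect * tech.sum(axis=1)
    if config.measurement_noise_sd_telseq > 0:
        telseq_raw = telseq_raw + config.measurement_noise_sd_telseq * rng.normal(size=n)
    qpcr_raw = latent.copy()
    art = annotations.index[annotations["qpcr_only"]]
    if len(art):
        qpcr_raw = qpcr_raw + genotypes[art].to_numpy(dtype=float) @ annotations.loc[
            art, "true_beta"
        ].to_numpy()
    if config.measurement_noise_sd_qpcr > 0:
        qpcr_raw = qpcr_raw + config.measurement_noise_sd_qpcr * rng.normal(size=n)
    measurements = pd.DataFrame(
        {"sample_id": cohort["sample_id"], "qpcr_raw": qpcr_raw, "telseq_raw": telseq_raw}
    )

    truth = TruthTable(
        latent_tl=latent,
        latent_tl_germline=latent_pre,
        genetic_score=genetic_score,
        tech_factors=tech,
        variant_effects=annotations[["id", "gene", "true_beta", "qpcr_only"]].copy(),
        burden_effects=pd.DataFrame(
            [
                {"gene": g, "carrier_freq": cf, "true_beta": eff / scale}
                for g, (cf, eff) in burden_carrier.items()
            ]
        ),
        ch_truth=ch.truth,
    )
    return SimulatedCohort(
        cohort, genotypes, annotations, coverage, measurements, ch.calls, truth
    )


def small_config(n_samples: int = 2000, seed: int = 7, **overrides) -> GeneratorConfig:
    """A reduced configuration for fast unit tests (fewer tiles and variants)."""
    cfg = GeneratorConfig(
        n_samples=n_samples,
        seed=seed,
        n_common_variants=10,
        n_rare_variants=12,
        n_tiles=80,
        allelic_series_spec=[("ACD", 5e-3, 1.0), ("ACD", 5e-3, -1.0)],
        burden_gene_spec=[("CTC1", 0.02, 0.8)],
        loo_gene_spec=("POT1", [(5e-3, 1.2), (1e-3, 0.0), (1e-3, 0.0)]),
        ld_pair_spec=("SAMHD1", 5e-3, 1.2, "SOGA1", 0.99),
    )
    return replace(cfg, **overrides) if overrides else cfg
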