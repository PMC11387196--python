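# Methods

## The problem

Population-scale telomere-length (TL) studies have two cheap instruments:
the qPCR T:S ratio (telomere repeat abundance relative to a single-copy
reference gene) and in-silico estimators such as TelSeq that count
telomere-motif reads in whole-genome sequencing (WGS). Both are noisy, and
each carries instrument-specific technical structure: WGS estimates inherit
genome-wide coverage confounding, and the qPCR assay can pick up genetic
variation at its reference gene (HBB) that has nothing to do with telomeres.
`telojoint` implements a pipeline that (i) removes coverage confounding from
the WGS estimate, (ii) combines the two measurements into a joint metric by
PCA — PC1 carrying the shared biological signal, PC2 the metric discordance
— and (iii) runs the downstream germline (common, rare, gene-collapsing)
and somatic (clonal hematopoiesis, CH) association stages, using PC2 as an
artifact detector.

## Coverage correction

The genome is split into 1-kb tiles (0-based, half-open); tiles overlapping
a mappability/blacklist/structural-variant mask by at least one base, or on
a non-autosome, are dropped with a reason code. Per-sample mean tile depth
is reconstructed from quantized (binned) coverage runs: each base
contributes the representative depth of its bin. The four default bins are
(0–9), (10–19), (20–49), (50+), with representatives 4.5, 14.5 and 34.5
(the medians of the closed integer ranges). The open top bin has no median;
we use 60 by default. Any fixed value preserves depth ordering and the
subsequent PCA absorbs the scale, so the correction is insensitive to this
choice.

Samples are randomly partitioned into batches (default 20,000 per batch,
last batch absorbing the remainder), each batch's coverage columns are
centered, the top `min(n_pcs, batch_n − 1, n_tiles)` principal components
are computed, and the raw telomere estimate is regressed (with intercept)
on the PC scores; the residual is the corrected estimate. The default is
300 PCs. Requests beyond the feasible rank are truncated with a warning; a
zero-variance coverage matrix degrades to mean-centering with a warning,
and no sample is ever dropped. The regression includes an intercept only
(column centering); whether a per-batch intercept beyond centering was
intended upstream is unknowable, and for residualization the two are
equivalent.

PC scores are obtained from an exact eigendecomposition of the Gram matrix
when the tile count is modest (≤3,000 columns), which is both cheaper and
bit-reproducible at this scale; very wide matrices use randomized SVD. The
two agree with exact SVD to relative error below 1e-6 at the ranks used,
which the suite checks directly.

## The joint metric

Both measurements are rank-based inverse-normal transformed (INT):
`z_i = Φ⁻¹((rank_i − c)/(n − 2c + 1))` with average ranks for ties and the
Blom offset c = 3/8 by default (c is configurable in [0, 0.5]; rank order,
and hence everything downstream, is invariant to it). All-equal input has
undefined ranks and raises.

Since both INT inputs have unit variance, PCA of their covariance equals
PCA of their correlation matrix, whose eigenvalues are 1 ± |r|. The
variance shares are therefore ((1+|r|)/2, (1−|r|)/2) in closed form; at the
two instruments' observed squared correlation r² = 0.29 this gives 76.9%
and 23.1%, i.e. 77%/23% to the nearest percent. Axis signs are not
identified by PCA, so we fix an orientation: PC1 loads positively on both
inputs (shared signal; it is numerically the standardized mean of the two
metrics), PC2 loads positively on qPCR (so it tracks qPCR − TelSeq).
Perfectly anti-correlated inputs admit no such orientation and raise.

Diagnostics: a joint age model (age ~ TelSeq + qPCR + sex) with variance
inflation factors and leave-one-metric-out ΔR²; a bootstrap age-prediction
benchmark (default: 100 replicates, 10,000 training samples drawn with
replacement, RMSE on the undrawn samples, all metrics sharing resamples so
comparisons are paired); and a Bland–Altman agreement analysis of the two
INT metrics with a logistic model of outlier status (default threshold
1.96 SD from the bias, configurable) on user-supplied covariates such as
carrier flags for a suspected reference-gene artifact.

## Association stages

*Common variants.* Per-variant ordinary least squares of the INT-scale
phenotype on dosage plus covariates (age, sex, age², ancestry PCs,
sequencing site, optionally genotyping plate), computed by
Frisch–Waugh–Lovell residualization so thousands of variants are scanned
with one QR factorization. In unrelated synthetic cohorts this is the
correct likelihood; the phenotype-vector interface leaves room for a
mixed-model backend on related cohorts. Variant QC: call-rate ≥99%
(missingness ≤ 0.01), imputation INFO ≥ 0.7, and a Hardy–Weinberg exact
test (full enumeration of heterozygote counts given allele counts,
probability-mass two-sided) excluding p < 1e-5 — the conventional filter
direction; the source material prints the inequality the other way around
once, which we treat as a typographical artifact and document rather than
follow.

*Loci.* Genome-wide-significant variants (p < 5e-8) are padded ±1 Mb; any
hit inside the MHC contributes the bespoke region chr6:25.5–34 Mb instead.
Half-open regions merge when overlapping or abutting, across phenotypes.
The index variant is the minimum-p member; exact p ties break by proximity
to the merged-region midpoint, then by smaller coordinate. Merging is
idempotent and order-independent.

*Artifact flagging.* A PC1-significant signal that is also PC2-significant
is flagged rather than reported (thresholds 5e-8 in GWAS mode, 1e-8 in the
rare-variant report). The planted qPCR-only variant in the generator
exercises exactly this path.

*Fine-mapping.* Wakefield's approximate Bayes factor per variant,
ABF = √(1−r)·exp(z²r/2) with r = W/(V+W), V = se², computed in logs. Under
a single-causal assumption with a flat prior over variants, posteriors are
PP_i = ABF_i/ΣABF_j per LD block, and the 95% credible set is the smallest
descending-PP prefix reaching 0.95. The prior effect variance defaults to
W = 0.15² = 0.0225, a standard choice for unit-variance quantitative
traits, configurable. LD blocks are supplied by the caller (default: one
block per locus). The calibration test simulates blocks from the matching
generative model (causal effects ~ N(0, W)) at moderate power (per-variant
se 0.05, so causal |z| has SD 3): in that regime the realized coverage of
the 95% set is near-nominal. At saturated power the discrete prefix
overshoots toward certain coverage — sets collapse to a single variant with
posterior ≈1 — which is expected behavior of credible-set constructions,
not miscalibration.

*Rare variants.* ExWAS tests each variant under genotypic (0/1/2),
dominant (0/1/1) and recessive (0/0/1) codings; the rare report keeps
MAF < 0.1% variants with ≥5 carriers under the best (most significant PC1)
coding and applies the PC1-not-PC2 rule. Collapsing aggregates qualifying
variants per gene into a 0/1 carrier indicator (allele-count coding
available) with the same covariates and a significance threshold of 1e-8;
ten named QV models (ptv, ptv5pcnt, UR, URmtr, raredmg, raredmgmtr,
ptvraredmg, flexdmg, flexnonsynmtr, and the synonymous empirical control)
define qualifying variants by consequence class, MAF ceiling, REVEL-like
deleteriousness floor and MTR-like constraint percentile; their exact
upstream thresholds are not public, so the presets are documented
conventions, configurable via YAML. Leave-one-out refits quantify each
variant's leverage on a gene signal (single-QV genes get an explicit
not-applicable result). Calibration is summarized by λ_GC =
median(χ²)/0.4549. Ancestry strata combine by fixed-effect
inverse-variance weighting, cross-checked against Stouffer's √n-weighted
z method, which should agree within an order of magnitude of p for
homogeneous effects.

*Clonal hematopoiesis.* Calls are filtered to 0.03 ≤ VAF ≤ 0.4 (closed
bounds) with allelic depth ≥3; samples with a prior hematological
malignancy or lymphocyte count > 5×10⁹/L are excluded (the same exclusion
operation gates the rare-variant stages). Multiple calls per sample and
gene collapse to the maximum VAF (clone-size proxy; summing is available).
VAF strata are 3–5%, >5–10%, >10–20%, >20% with closed upper bounds, a
partition of the filtered range. Carrier association uses a main-effects
model (carrier + age + sex + age² + ancestry PCs 1–4 + ever-smoked +
pack-years); smoking covariates are complete-case by default. The ordinal
trend model recodes carrier status as the stratum index (0 = non-carrier,
1–4 = strata), so the slope sign reads as the direction of TL change with
clone size; genes whose carriers occupy fewer than two strata are flagged
not-estimable.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, at a
desk scale of n = 20,000 samples and 500 coverage tiles (the biobank-scale
analysis uses ~480k samples and ~178k tiles; all estimators here are
n-consistent and the suite's recovery margins are set for the desk scale).
A latent standardized TL trait is composed of an age effect (−0.30 SD per
SD of age, ages uniform 40–70), a sex effect (+0.10), small ancestry-PC
effects, planted genetic effects, and Gaussian residual sized so the total
variance is 1. Planted genetics comprise: 50 common variants with effects
~N(0, 0.05); a rare allelic series in one gene (two lengthening, two
shortening missense variants, effects +2.55/+2.49/−0.90/−1.41 SD at MAFs
1.6e-4–7.1e-4 — a biobank-patterned series with effects tripled for power
at n = 20k); a burden gene (six PTVs, 1% aggregate carrier frequency,
+0.7 SD carrier effect); a driver-plus-passengers gene for leave-one-out;
and a rare LD-contamination pair (causal variant plus an effect-free shadow
at dosage correlation 0.99, generated by copy-with-redraw).

Measurements: raw TelSeq = latent TL + 0.5·(sum of three standard-normal
technical factors) + N(0, 0.93²); raw qPCR = latent TL + artifact effect ×
artifact dosage + N(0, 0.93²). The artifact variant (MAF 0.10, −0.5 on the
qPCR reading only) emulates reference-gene interference: it shifts the
qPCR value without touching TL, so it surfaces on qPCR and PC2 but not
TelSeq. The technical factors also load on every coverage tile (loadings
~N(0,1) depth units) on top of a per-sample mean depth ~N(32.5, 2²) and
tile noise, so coverage PCA can find and remove them. The measurement
noise SD (0.93 on both instruments) was fixed once from the closed form
r² = 1/((1+σ_q²)(1+σ_t²)) so that, after correction, the two processed
metrics agree at r² ≈ 0.29.

CH drivers are simulated per gene with a logistic acquisition model in
standardized age and latent TL, and a clone-size effect on TL of
`vaf_to_tl × VAF` applied before measurement — the "cause" (TL → clone)
and "effect" (clone → TL) directions are separate parameters so either can
be planted alone. Defaults: a DNMT3A-analog (acquisition favored by long
telomeres, no clone effect), a TET2-like attrition analog (clone shortens
TL in proportion to VAF), and an SRSF2-analog (acquisition slightly favored
by short telomeres, large clones lengthen TL). Reported VAF is AD/DP at an
exome-like depth (~120×) with Beta-distributed true clone fractions
rescaled to (0.01, 0.45), so the printed VAF/AD filters have genuine work
to do.

Everything derives from one seeded `numpy` Generator: identical config and
seed reproduce all outputs bit for bit. Planted rare variants are
conditioned on at least one realized carrier (redrawn inside the seeded
stream); configurations whose planted signals expect fewer than one
carrier are rejected up front.

What the generator does *not* emulate: linkage disequilibrium beyond
explicit pairs, discrete ancestry strata (multi-ancestry analyses are
emulated by running the generator per stratum), X-chromosome dosage,
read-level sequence noise, and relatedness. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
sampling model, not robustness to population structure or cryptic
relatedness in real cohorts.

## Numerical choices and degenerate inputs

- Half-open 0-based intervals for tiles/masks/loci; variant ids are
  1-based `chrom-pos-ref-alt`. Abutting loci merge.
- OLS p-values use the t distribution with n − k − 1 df; CIs are
  beta ± 1.96·se.
- Residualized predictors with sum of squares ≤ 1e-10×scale are treated as
  constant/collinear and skipped with a reason.
- The HWE exact test enumerates in log space and sums probabilities ≤ the
  observed configuration's (with a 1+1e-12 slack for float ties).
- ABF normalization subtracts the max log-ABF before exponentiation.
- λ_GC uses the χ²(1) null median 0.4549364.
- Bland–Altman outliers with zero difference SD: no outliers by definition.

## Limitations

OLS association assumes unrelated samples and homoskedastic residuals; the
collapsing carrier indicator ignores zygosity within genes; the credible
sets assume a single causal variant per block; QV presets approximate, not
replicate, proprietary model definitions; and the generator's calibration
constant (r² ≈ 0.29) is a property of the shipped defaults, not a law —
changing noise or technical-effect parameters moves it as the closed form
predicts.
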