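"""HWE exact test, QC, per-variant OLS, loci, ABF fine-mapping, prioritization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from telojoint import gwas
from telojoint.gwas import (
    FinemapParams,
    QCThresholds,
    abf_finemap,
    conditional_scan,
    define_loci,
    flag_artifact_signals,
    gwas_linear,
    hwe_exact_test,
    prioritize_genes,
    variant_qc,
    wakefield_abf,
)
from telojoint.rarevar import lambda_gc


def _enumerated_hwe(n_AA, n_AB, n_BB):
    """Independent oracle: direct enumeration with exact rational-ish math."""
    from math import comb

    n = n_AA + n_AB + n_BB
    rare = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    denom = comb(2 * n, rare)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        from math import factorial

        ways = factorial(n) // (factorial(hom_r) * factorial(het) * factorial(hom_c))
        probs[het] = ways * 2**het / denom
    p_obs = probs[n_AB]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (50, 0, 50), (30, 40, 10), (5, 5, 5)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(_enumerated_hwe(*counts), rel=1e-10)

    def test_modal_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    def test_monomorphic_site_is_uninformative(self):
        assert hwe_exact_test(0, 0, 100) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestVariantQC:
    def _ann(self, **kw):
        base = {"missingness": 0.0, "info": 1.0, "hwe_p": 0.5}
        base.update(kw)
        return pd.DataFrame([base], index=["v1"])

    def test_low_info_excluded(self):
        out = variant_qc(self._ann(info=0.69))
        assert not out["keep"].iloc[0] and out["qc_reason"].iloc[0] == "info"

    def test_perfect_variant_kept(self):
        assert variant_qc(self._ann())["keep"].iloc[0]

    def test_hwe_departure_excluded(self):
        out = variant_qc(self._ann(hwe_p=1e-6))
        assert not out["keep"].iloc[0] and out["qc_reason"].iloc[0] == "hwe"

    def test_high_missingness_excluded(self):
        assert not variant_qc(self._ann(missingness=0.02))["keep"].iloc[0]

    def test_hwe_computed_from_genotype_counts_when_missing(self):
        ann = pd.DataFrame(
            [{"missingness": 0.0, "info": 1.0, "n_AA": 50, "n_AB": 0, "n_BB": 50}],
            index=["v1"],
        )
        out = variant_qc(ann)
        assert not out["keep"].iloc[0] and out["qc_reason"].iloc[0] == "hwe"


class TestGwasLinear:
    def test_planted_effect_ci_coverage(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            g = rng.binomial(2, 0.2, size=2000).astype(float)
            y = 0.5 * g + rng.normal(size=2000)
            res = gwas_linear(y, pd.DataFrame({"v": g}))
            hits += res["ci_low"].iloc[0] <= 0.5 <= res["ci_high"].iloc[0]
        assert 0.90 <= hits / reps <= 0.99

    def test_null_scan_is_calibrated(self, sim, phenotypes, covars):
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(phenotypes))
        common = sim.annotations.index[sim.annotations["maf"] >= 0.05]
        res = gwas_linear(
            phenotypes["pc1"].to_numpy()[perm], sim.genotypes[list(common)], covars
        )
        # ~50 variants: the median-based lambda is far too noisy here, so
        # assess calibration by uniformity of the p-values instead
        assert stats.kstest(res["p"].dropna(), "uniform").pvalue > 0.001

    def test_null_scan_lambda_near_one_at_scale(self):
        rng = np.random.default_rng(19)
        n, m = 2000, 5000
        y = rng.normal(size=n)
        G = rng.binomial(2, rng.uniform(0.05, 0.5, size=m), size=(n, m))
        res = gwas_linear(y, pd.DataFrame(G))
        assert 0.9 < lambda_gc(res["p"].dropna()) < 1.1

    def test_constant_dosage_skipped_with_reason(self):
        y = np.random.default_rng(13).normal(size=100)
        res = gwas_linear(y, pd.DataFrame({"v": np.zeros(100)}))
        assert res["skipped"].iloc[0]
        assert res["reason"].iloc[0] == "constant-or-collinear-dosage"


class TestLoci:
    def _res(self, rows):
        return pd.DataFrame(rows, columns=["id", "chrom", "pos", "p"])

    def test_single_hit_padded_one_megabase(self):
        out = define_loci(self._res([("v1", "chr1", 5_000_000, 1e-9)]))
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (4_000_000, 6_000_000)
        assert row["index_variant"] == "v1"

    def test_hits_within_two_megabases_merge(self):
        out = define_loci(
            self._res(
                [("v1", "chr1", 5_000_000, 1e-9), ("v2", "chr1", 6_500_000, 1e-10)]
            )
        )
        assert len(out) == 1
        assert out.iloc[0]["index_variant"] == "v2"
        assert out.iloc[0]["n_members"] == 2

    def test_mhc_hit_uses_bespoke_region(self):
        out = define_loci(self._res([("v1", "chr6", 30_000_000, 1e-9)]))
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (25_500_000, 34_000_000)

    def test_empty_input_empty_output(self):
        assert define_loci(self._res([])).empty

    def test_tie_broken_by_midpoint_proximity(self):
        out = define_loci(
            self._res(
                [("far", "chr2", 4_000_000, 1e-9), ("near", "chr2", 5_000_000, 1e-9)]
            )
        )
        # merged region 3-6 Mb, midpoint 4.5 Mb; 'far' at 4.0 vs 'near' at 5.0
        assert out.iloc[0]["index_variant"] == "far"

    def test_merging_is_order_independent_and_idempotent(self):
        rows = [
            ("a", "chr1", 1_500_000, 1e-9),
            ("b", "chr1", 2_800_000, 1e-12),
            ("c", "chr1", 9_000_000, 1e-9),
            ("d", "chr2", 9_000_000, 1e-9),
        ]
        out1 = define_loci(self._res(rows))
        out2 = define_loci(self._res(rows[::-1]))
        assert out1[["chrom", "start", "end", "index_variant"]].equals(
            out2[["chrom", "start", "end", "index_variant"]]
        )
        members = [m for ms in out1["members"] for m in ms]
        assert sorted(members) == ["a", "b", "c", "d"]  # each hit in exactly one locus


class TestArtifactFlag:
    def test_planted_artifact_variant_is_flagged(self, sim, phenotypes, covars):
        art_id = sim.annotations.index[sim.annotations["qpcr_only"]][0]
        G = sim.genotypes[[art_id]]
        res = {
            name: gwas_linear(phenotypes[name].to_numpy(), G, covars)
            for name in ("pc1", "pc2", "qpcr", "telseq")
        }
        assert res["qpcr"]["p"].iloc[0] < 5e-8  # visible in the qPCR instrument
        assert res["pc2"]["p"].iloc[0] < 5e-8  # and on the discordance axis
        assert res["telseq"]["p"].iloc[0] > 0.01  # silent in the WGS instrument
        flags = flag_artifact_signals(res["pc1"], res["pc2"])
        assert flags["status"].iloc[0] == "flagged"

    def test_shared_signal_is_clean_and_null_is_unreported(self):
        pc1 = pd.DataFrame({"id": ["s", "n"], "p": [1e-10, 0.5]})
        pc2 = pd.DataFrame({"id": ["s", "n"], "p": [0.3, 0.6]})
        out = flag_artifact_signals(pc1, pc2).set_index("id")
        assert out.loc["s", "status"] == "clean"
        assert out.loc["n", "status"] == "not-significant"


class TestABF:
    def _bf_oracle(self, beta, se, W):
        """Brute-force Bayes factor: numerically integrate the marginal likelihood."""
        V = se**2

        def integrand(b):
            return stats.norm.pdf(beta, b, np.sqrt(V)) * stats.norm.pdf(b, 0, np.sqrt(W))

        marg1, _ = quad(integrand, -10, 10, limit=200)
        marg0 = stats.norm.pdf(beta, 0, np.sqrt(V))
        return marg1 / marg0

    def test_single_variant_block_gets_probability_one(self):
        block = pd.DataFrame({"id": ["v1"], "beta": [0.1], "se": [0.02]})
        out = abf_finemap(block)
        assert out["pp"].iloc[0] == pytest.approx(1.0)
        assert out["in_credible_set"].all()

    def test_two_variant_posterior_matches_formula(self):
        W = 0.0225
        se = 0.05
        block = pd.DataFrame({"id": ["a", "b"], "beta": [5 * se, 0.0], "se": [se, se]})
        out = abf_finemap(block, FinemapParams(W=W)).set_index("id")
        r = W / (se**2 + W)
        abf_a = np.sqrt(1 - r) * np.exp(25 * r / 2)
        abf_b = np.sqrt(1 - r)
        assert out.loc["a", "pp"] == pytest.approx(abf_a / (abf_a + abf_b), rel=1e-12)
        assert out.loc["a", "in_credible_set"] and not out.loc["b", "in_credible_set"]

    def test_posteriors_match_integration_oracle_on_three_variant_toys(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            betas = rng.normal(0, 0.1, size=3)
            ses = rng.uniform(0.02, 0.1, size=3)
            block = pd.DataFrame({"id": list("abc"), "beta": betas, "se": ses})
            out = abf_finemap(block).sort_values("id")
            bfs = np.array([self._bf_oracle(b, s, 0.0225) for b, s in zip(betas, ses)])
            expected = bfs / bfs.sum()
            np.testing.assert_allclose(out["pp"].to_numpy(), expected, rtol=1e-6)

    def test_missing_se_dropped_with_warning(self):
        block = pd.DataFrame({"id": ["a", "b"], "beta": [0.1, 0.2], "se": [0.05, np.nan]})
        with pytest.warns(UserWarning, match="without usable se"):
            out = abf_finemap(block)
        assert list(out["id"]) == ["a"]

    def test_credible_set_coverage_under_generative_model(self):
        """500 single-causal blocks: the 95% set should cover ~95% of causals."""
        rng = np.random.default_rng(15)
        W, se, m = 0.0225, 0.05, 50
        covered = 0
        for _ in range(500):
            causal = rng.integers(m)
            beta_true = rng.normal(0, np.sqrt(W))
            z = rng.normal(size=m)
            z[causal] += beta_true / se
            block = pd.DataFrame(
                {"id": np.arange(m), "beta": z * se, "se": np.full(m, se)}
            )
            out = abf_finemap(block)
            covered += bool(out.set_index("id").loc[causal, "in_credible_set"])
        assert 0.93 <= covered / 500 <= 0.97


class TestConditional:
    def test_empty_conditioning_set_equals_marginal(self):
        rng = np.random.default_rng(16)
        g = rng.binomial(2, 0.3, size=500).astype(float)
        y = 0.3 * g + rng.normal(size=500)
        marg = gwas_linear(y, pd.DataFrame({"v": g})).iloc[0]
        cond = conditional_scan(y, g, None)
        assert cond["beta"] == pytest.approx(marg["beta"])
        assert cond["p"] == pytest.approx(marg["p"])

    def test_target_equal_to_conditioning_variant_rejected(self):
        g = np.random.default_rng(17).binomial(2, 0.3, size=100).astype(float)
        with pytest.raises(ValueError, match="duplicated"):
            conditional_scan(np.random.normal(size=100), g, pd.DataFrame({"c": g}))

    def test_ld_shadow_signal_nullified(self, sim, phenotypes, covars):
        ann = sim.annotations
        causal_id = ann.index[(ann["gene"] == "SAMHD1") & (ann["true_beta"] != 0)][0]
        shadow_id = ann.index[ann["gene"] == "SOGA1"][0]
        y = phenotypes["pc1"].to_numpy()
        marg = gwas_linear(y, sim.genotypes[[shadow_id]], covars)
        assert marg["p"].iloc[0] < 1e-6  # LD makes the shadow look real
        cond = conditional_scan(
            y, sim.genotypes[shadow_id].to_numpy(), sim.genotypes[[causal_id]], covars
        )
        assert cond["p"] > 0.05

    def test_orthogonal_conditioning_changes_little(self):
        rng = np.random.default_rng(18)
        g = rng.binomial(2, 0.3, size=2000).astype(float)
        other = rng.binomial(2, 0.3, size=2000).astype(float)
        y = 0.3 * g + rng.normal(size=2000)
        marg = gwas_linear(y, pd.DataFrame({"v": g})).iloc[0]
        cond = conditional_scan(y, g, pd.DataFrame({"c": other}))
        assert abs(cond["beta"] - marg["beta"]) < marg["se"]


class TestPrioritization:
    def test_score_is_category_sum_and_max_wins(self):
        ev = pd.DataFrame(
            {"c1": [1, 1, 0], "c2": [1, 0, 0], "c3": [1, 0, 0]},
            index=["g1", "g2", "g3"],
        )
        out = prioritize_genes(ev, {"g1": "L1", "g2": "L1", "g3": "L1"})
        row = out.iloc[0]
        assert row["score"] == 3
        assert row["prioritized_genes"] == ["g1"]
        assert row["single_gene_prioritized"]

    def test_all_zero_evidence_prioritizes_nothing(self):
        ev = pd.DataFrame({"c1": [0, 0]}, index=["g1", "g2"])
        out = prioritize_genes(ev, {"g1": "L1", "g2": "L1"})
        assert out.iloc[0]["prioritized_genes"] == []
        assert not out.iloc[0]["single_gene_prioritized"]

    def test_tied_maximum_is_not_single_gene(self):
        ev = pd.DataFrame({"c1": [1, 1]}, index=["g1", "g2"])
        out = prioritize_genes(ev, {"g1": "L1", "g2": "L1"})
        assert sorted(out.iloc[0]["prioritized_genes"]) == ["g1", "g2"]
        assert not out.iloc[0]["single_gene_prioritized"]
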