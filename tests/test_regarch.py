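"""Hotspots, cis-trans mode classification, LD permutation, MAF and pi."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salexpr import regarch
from salexpr import synthdata as sd
from tests.test_respond import geno_from_dosage


def record(snp, beta, p=1e-6, pos=1000, chrom="chr1", gene="g", cls="cis"):
    return pd.DataFrame({
        "snp": [snp], "chrom": [chrom], "pos": [pos], "gene": [gene],
        "beta": [beta], "t": [5.0], "p": [p], "q": [p], "class": [cls],
        "lead": [True],
    })


def linked_pair_genotypes(n_acc, flip_prob, seed=0, n_extra=0):
    """Two {0,2} SNPs in LD (r ~ 1 - 2*flip_prob) plus optional noise SNPs."""
    rng = np.random.default_rng(seed)
    xc = rng.choice([0, 2], n_acc)
    flip = rng.uniform(size=n_acc) < flip_prob
    xt = np.where(flip, 2 - xc, xc)
    cols = [xc, xt] + [rng.choice([0, 2], n_acc) for _ in range(n_extra)]
    return geno_from_dosage(np.column_stack(cols))


class TestDetectHotspots:
    def _leads(self, n_genes, pos=50_000):
        return pd.DataFrame({
            "snp": ["s_h"] * n_genes, "chrom": ["chr2"] * n_genes,
            "pos": [pos] * n_genes, "gene": [f"g{i}" for i in range(n_genes)],
            "beta": 1.0, "t": 5.0, "p": 1e-9, "q": 1e-6,
            "class": "trans", "lead": True,
        })

    def test_thirty_one_genes_is_hotspot(self):
        out = regarch.detect_hotspots(self._leads(31))
        assert len(out) == 1 and out["n_genes"].iloc[0] == 31

    def test_thirty_genes_is_not(self):
        assert len(regarch.detect_hotspots(self._leads(30))) == 0

    def test_empty_records(self):
        assert regarch.detect_hotspots(self._leads(0)).empty


class TestClassifyMode:
    def test_same_direction_majority_reinforcing(self):
        g = linked_pair_genotypes(200, flip_prob=0.1, seed=1)
        call = regarch.classify_mode(
            "g", record("s0", 1.0), record("s1", 0.8, cls="trans"), g
        )
        assert call.mode == "reinforcing"
        assert call.frac_same >= 0.6

    def test_opposite_direction_majority_compensating(self):
        g = linked_pair_genotypes(200, flip_prob=0.1, seed=2)
        call = regarch.classify_mode(
            "g", record("s0", 1.0), record("s1", -0.8, cls="trans"), g
        )
        assert call.mode == "compensating"

    def test_balanced_configuration_unclassified(self):
        g = linked_pair_genotypes(400, flip_prob=0.5, seed=3)
        call = regarch.classify_mode(
            "g", record("s0", 1.0), record("s1", 0.8, cls="trans"), g
        )
        assert call.mode == "unclassified"

    def test_invariant_to_allele_relabeling(self):
        g = linked_pair_genotypes(150, flip_prob=0.15, seed=4)
        flipped = geno_from_dosage(2 - g.dosage)
        a = regarch.classify_mode("g", record("s0", 1.0),
                                  record("s1", 0.8, cls="trans"), g)
        # relabeling both alleles flips both betas and both dosage centerings
        b = regarch.classify_mode("g", record("s0", -1.0),
                                  record("s1", -0.8, cls="trans"), flipped)
        assert a.mode == b.mode
        assert a.frac_same == pytest.approx(b.frac_same)

    def test_accuracy_degrades_as_ld_decays(self):
        acc = []
        for flip in (0.05, 0.25, 0.5):
            hits = 0
            for rep in range(40):
                g = linked_pair_genotypes(150, flip, seed=100 * rep + int(flip * 100))
                call = regarch.classify_mode(
                    "g", record("s0", 1.0), record("s1", 0.9, cls="trans"), g
                )
                hits += call.mode == "reinforcing"
            acc.append(hits / 40)
        assert acc[0] > 0.9
        assert acc[0] >= acc[1] >= acc[2] - 0.1
        assert acc[2] < 0.6


class TestSummarizeModes:
    def _calls(self, n_re, n_co):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(n_re + n_co)],
            "mode": ["reinforcing"] * n_re + ["compensating"] * n_co,
        })

    def test_paper_worked_example(self):
        out = regarch.summarize_modes(self._calls(317, 207))
        assert out["p"] == pytest.approx(1.65e-11, rel=5e-3)

    def test_equal_counts_give_p_one(self):
        out = regarch.summarize_modes(self._calls(50, 50))
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_small_counts_direction_agrees_with_exact_binomial(self):
        # the z-test on paired proportions is more liberal than the exact
        # binomial; the direction of the excess must agree, and an exact-test
        # significant split must also be significant under the z-test
        for n_re, n_co in ((8, 2), (9, 1), (6, 4)):
            out = regarch.summarize_modes(self._calls(n_re, n_co))
            p_exact = stats.binomtest(n_re, n_re + n_co, 0.5).pvalue
            assert out["n_reinforcing"] > out["n_compensating"]
            if p_exact < 0.05:
                assert out["p"] < 0.05

    def test_no_classified_genes_rejected(self):
        with pytest.raises(ValueError):
            regarch.summarize_modes(pd.DataFrame({"gene": ["g"],
                                                  "mode": ["unclassified"]}))


class TestModeExpressionContrast:
    def _calls(self):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(6)],
            "mode": ["reinforcing"] * 3 + ["compensating"] * 3,
        })

    def test_hand_rank_sum_fixture(self):
        # reinforcing {4,5,6} vs compensating {1,2,3}: exact one-sided p = 1/20
        iv = pd.Series([4.0, 5, 6, 1, 2, 3],
                       index=[f"g{i}" for i in range(6)])
        out = regarch.mode_expression_contrast(self._calls(), iv)
        assert out["p"] == pytest.approx(0.05, abs=1e-10)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        calls = pd.DataFrame({"gene": genes,
                              "mode": ["reinforcing"] * 100 +
                                      ["compensating"] * 100})
        iv = pd.Series(np.concatenate([rng.normal(1, 1, 100),
                                       rng.normal(0, 1, 100)]), index=genes)
        assert regarch.mode_expression_contrast(calls, iv)["p"] < 0.01

    def test_empty_group_rejected(self):
        iv = pd.Series([1.0] * 6, index=[f"g{i}" for i in range(6)])
        calls = self._calls()
        calls["mode"] = "reinforcing"
        with pytest.raises(ValueError):
            regarch.mode_expression_contrast(calls, iv)


class TestLdPermutationTest:
    def test_duplicated_snp_pair_r2_one(self, small_geno):
        poly = np.flatnonzero(small_geno.maf() > 0.1)
        s = str(small_geno.snp_ids[poly[0]])
        out = regarch.ld_permutation_test([(s, s)], small_geno, n_perm=50, seed=0)
        assert out["observed_mean_r2"] == pytest.approx(1.0)

    def test_planted_ld_pairs_significant(self):
        g = sd.simulate_genotypes(
            100, {"chr1": 10_000_000, "chr2": 10_000_000}, 600,
            seed=6, ld_block=200_000,
        )
        # pairs inside one LD block are strongly correlated by construction
        pairs = []
        for c in ("chr1", "chr2"):
            ix = np.flatnonzero((g.chrom == c) & (g.maf() > 0.1))
            for k in range(0, len(ix) - 1, 8):
                a, b = ix[k], ix[k + 1]
                if abs(g.pos[a] - g.pos[b]) < 150_000:
                    pairs.append((str(g.snp_ids[a]), str(g.snp_ids[b])))
                if len(pairs) >= 15:
                    break
        out = regarch.ld_permutation_test(pairs, g, n_perm=300, seed=7,
                                          distance_tol=0.5)
        assert out["observed_mean_r2"] > out["null_mean_r2"]
        assert out["p"] <= 20 / 301

    def test_null_pairs_give_large_p(self, small_geno):
        rng = np.random.default_rng(8)
        ids = small_geno.snp_ids
        pairs = []
        while len(pairs) < 10:
            a, b = rng.integers(0, len(ids), 2)
            if small_geno.chrom[a] != small_geno.chrom[b]:
                pairs.append((str(ids[a]), str(ids[b])))
        out = regarch.ld_permutation_test(pairs, small_geno, n_perm=200, seed=9)
        assert out["p"] > 0.05

    def test_empty_pairs_rejected(self, small_geno):
        with pytest.raises(ValueError):
            regarch.ld_permutation_test([], small_geno)


class TestMafContrast:
    def test_hand_arithmetic(self):
        # minor-allele count 10 over 130 inbred accessions = 260 haploid
        # equivalents: MAF = 10/260
        d = np.zeros((130, 2), np.int8)
        d[:5, 0] = 2
        d[:40, 1] = 2
        g = geno_from_dosage(d)
        assert g.maf()[0] == pytest.approx(10 / 260, abs=1e-10)

    def test_identical_sets_give_null_test(self):
        d = np.zeros((40, 4), np.int8)
        for j in range(4):
            d[: 5 * (j + 1), j] = 2
        g = geno_from_dosage(d)
        out = regarch.maf_contrast({"a": list(g.snp_ids),
                                    "b": list(g.snp_ids)}, g)
        t = out["tests"][("a", "b")]
        assert t["t"] == pytest.approx(0.0, abs=1e-12)
        assert t["p"] == pytest.approx(1.0)

    def test_planted_left_shift_detected(self):
        rng = np.random.default_rng(10)
        low = (rng.uniform(size=(400, 500)) < 0.09).astype(np.int8) * 2
        high = (rng.uniform(size=(400, 500)) < 0.20).astype(np.int8) * 2
        g = geno_from_dosage(np.column_stack([low, high]))
        sets = {"eqtl": [f"s{j}" for j in range(500)],
                "background": [f"s{j}" for j in range(500, 1000)]}
        out = regarch.maf_contrast(sets, g)
        assert out["mean_maf"]["eqtl"] < out["mean_maf"]["background"]
        assert out["tests"][("background", "eqtl")]["p"] < 1e-6

    def test_tiny_set_skipped(self):
        d = np.tile([0, 2], (20, 2)).astype(np.int8).reshape(20, -1)
        g = geno_from_dosage(d[:, :3])
        out = regarch.maf_contrast({"one": [str(g.snp_ids[0])],
                                    "rest": list(g.snp_ids)}, g)
        assert "one" not in out["mean_maf"]


class TestPi:
    def test_monomorphic_site_zero(self):
        g = geno_from_dosage(np.zeros((10, 1), np.int8))
        assert regarch.site_pi(g)[0] == 0.0

    def test_hand_arithmetic(self):
        # p = 0.5 over n = 10 haploid-equivalents: pi = 0.5 * 10/9
        d = np.array([[2]] * 5 + [[0]] * 5, np.int8)
        g = geno_from_dosage(d)
        assert regarch.site_pi(g)[0] == pytest.approx(2 * 0.25 * 10 / 9)

    def test_planted_high_diversity_flanks_detected(self):
        rng = np.random.default_rng(11)
        n_acc, n_snps = 80, 400
        # first 100 SNPs (positions 1..100 kb) near 0.5 frequency, rest rare
        p = np.r_[np.full(100, 0.5), np.full(n_snps - 100, 0.06)]
        d = (rng.uniform(size=(n_acc, n_snps)) < p).astype(np.int8) * 2
        g = geno_from_dosage(d)  # positions are 1000*(j+1)
        cis = [str(g.snp_ids[j]) for j in (20, 50, 80)]
        out = regarch.pi_contrast(g, cis, flank=25_000, block=50_000)
        assert out["window_pi_mean"] > out["background_pi_mean"]
        assert out["p"] < 0.01
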