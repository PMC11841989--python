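"""Selection differentials, gradients, trade-off classes, GO statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salexpr import selscan
from salexpr.datatypes import FitnessTable
from tests.conftest import make_expression


def make_fitness(expr, fecundity):
    return FitnessTable(
        plant_ids=expr.plant_ids,
        fecundity=np.asarray(fecundity, np.int64),
        environment=expr.environment,
        block=expr.block,
    )


class TestRelativeFitness:
    def test_constant_fecundity_gives_unit_fitness(self):
        rf = selscan.relative_fitness([10, 10, 10])
        assert np.allclose(rf.w, 1.0)

    def test_zeros_dropped_hand_arithmetic(self):
        rf = selscan.relative_fitness([0, 10, 20])
        assert rf.retained.tolist() == [False, True, True]
        assert rf.w == pytest.approx([2 / 3, 4 / 3])

    def test_mean_is_one_by_construction(self):
        rng = np.random.default_rng(0)
        rf = selscan.relative_fitness(rng.integers(1, 500, 100))
        assert rf.w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            selscan.relative_fitness([0, 0, 0])


class TestTrimOutliers:
    def test_constant_vector_unchanged(self):
        assert selscan.trim_outliers([5.0] * 10).all()

    def test_planted_outlier_masked(self):
        rng = np.random.default_rng(1)
        x = np.append(rng.normal(size=100), 8.0)
        keep = selscan.trim_outliers(x)
        assert not keep[-1]
        # brute-force: exactly the values beyond 3 SD are masked
        expect = np.abs(x - x.mean()) <= 3 * x.std(ddof=1)
        assert np.array_equal(keep, expect)

    def test_infinite_k_keeps_everything(self):
        assert selscan.trim_outliers([1.0, 2.0, 100.0], k=np.inf).all()


class TestSelectionDifferentials:
    def test_constant_fitness_gives_null_estimates(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.uniform(1, 5, size=(40, 3)))
        tab = selscan.selection_differentials(
            expr, make_fitness(expr, [50] * 40), "normal"
        )
        assert np.allclose(tab["S"], 0.0, atol=1e-12)
        assert np.allclose(tab["C"], 0.0, atol=1e-10)

    def test_noiseless_linear_fitness_exact(self):
        # x in {1..5}, fecundity = 1000 + 300*(x-3): w = 1 + 0.3*(x - 3)
        x = np.tile([1.0, 2, 3, 4, 5], 6)
        expr = make_expression(x[:, None])
        fec = 1000 + 300 * (x - 3)
        tab = selscan.selection_differentials(expr, make_fitness(expr, fec),
                                              "normal")
        assert tab["S"].iloc[0] == pytest.approx(0.3, abs=1e-12)
        assert tab["p_S"].iloc[0] < 1e-10

    def test_noiseless_quadratic_fitness_exact(self):
        # w = 1 + 0.1*((x-3)^2 - 2) on x in {1..5}: C = 0.2, S = 0
        x = np.tile([1.0, 2, 3, 4, 5], 6)
        expr = make_expression(x[:, None])
        fec = 1000 * (1 + 0.1 * ((x - 3) ** 2 - 2))
        tab = selscan.selection_differentials(expr, make_fitness(expr, fec),
                                              "normal")
        assert tab["C"].iloc[0] == pytest.approx(0.2, abs=1e-12)
        assert tab["S"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardization_identities(self):
        rng = np.random.default_rng(3)
        expr = make_expression(rng.uniform(1, 6, size=(60, 5)))
        fec = rng.integers(10, 300, 60)
        tab = selscan.selection_differentials(expr, make_fitness(expr, fec),
                                              "normal")
        ok = tab["skipped"] == ""
        assert np.allclose(tab.loc[ok, "S_s"],
                           tab.loc[ok, "S"] * tab.loc[ok, "sigma_z"])
        assert np.allclose(tab.loc[ok, "S_m"],
                           tab.loc[ok, "S"] * tab.loc[ok, "mu_z"])

    def test_low_expression_transcript_skipped(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 5, size=(40, 2))
        vals[5:, 1] = 0.0  # expressed in only 5 plants
        expr = make_expression(vals)
        tab = selscan.selection_differentials(
            expr, make_fitness(expr, rng.integers(1, 100, 40)), "normal"
        )
        assert tab.loc["t1", "skipped"] == "min_n"


class TestClassifyCnAp:
    def _tables(self, p_n, p_s, s_n=1.0, s_s=1.0):
        tn = pd.DataFrame({"S": [s_n], "p_S": [p_n]}, index=["t"])
        ts = pd.DataFrame({"S": [s_s], "p_S": [p_s]}, index=["t"])
        return tn, ts

    @pytest.mark.parametrize(
        "p_n,p_s,s_n,s_s,expected",
        [
            (0.01, 0.60, 1.0, 1.0, "CN_normal"),
            (0.60, 0.01, 1.0, 1.0, "CN_saline"),
            (0.02, 0.03, 1.0, -1.0, "AP"),
            (0.02, 0.03, 1.0, 1.0, "concordant"),
            (0.03, 0.60, 1.0, 1.0, "none"),  # CN needs p < 0.025
            (0.30, 0.30, 1.0, -1.0, "none"),
        ],
    )
    def test_threshold_rules(self, p_n, p_s, s_n, s_s, expected):
        labels = selscan.classify_cn_ap(*self._tables(p_n, p_s, s_n, s_s))
        assert labels["t"] == expected

    def test_missing_values_give_none(self):
        labels = selscan.classify_cn_ap(*self._tables(np.nan, 0.01))
        assert labels["t"] == "none"


class TestExpressionPca:
    def test_rank_one_matrix(self):
        u = np.linspace(0, 1, 20)[:, None]
        v = np.linspace(1, 2, 6)[None, :]
        res = selscan.expression_pca(make_expression(u * v + 1))
        assert res.var_frac[0] > 0.999

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        res = selscan.expression_pca(make_expression(rng.uniform(0, 3, (30, 8))))
        assert res.var_frac.sum() == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 3, (25, 7))
        res = selscan.expression_pca(make_expression(vals))
        recon = res.scores @ res.loadings.T + vals.mean(axis=0)
        assert np.allclose(recon, vals, atol=1e-6)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            selscan.expression_pca(make_expression(np.ones((5, 4))))


class TestSelectionGradients:
    def test_noiseless_planted_betas_exact(self):
        rng = np.random.default_rng(7)
        scores = np.linalg.qr(rng.normal(size=(50, 2)))[0]  # orthogonal
        w = 1 + 0.2 * scores[:, 0] - 0.1 * scores[:, 1]
        out = selscan.selection_gradients(scores, w)
        assert out["beta"].to_numpy() == pytest.approx([0.2, -0.1], abs=1e-10)

    def test_constant_fitness_gives_zero(self):
        rng = np.random.default_rng(8)
        out = selscan.selection_gradients(rng.normal(size=(30, 3)), np.ones(30))
        assert np.allclose(out[["beta", "gamma"]], 0.0, atol=1e-10)

    def test_quadratic_recovery_matches_brute_force(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(60, 2))
        w = 1 + 0.1 * scores[:, 0] - 0.15 * scores[:, 1] ** 2
        out = selscan.selection_gradients(scores, w)
        x = np.column_stack([np.ones(60), scores, scores**2])
        coef = np.linalg.lstsq(x, w, rcond=None)[0]
        assert out["gamma"].to_numpy() == pytest.approx(2 * coef[3:], abs=1e-8)

    def test_collinear_scores_rejected(self):
        s = np.ones((30, 1)) @ np.ones((1, 2))
        with pytest.raises(ValueError):
            selscan.selection_gradients(s, np.ones(30))


class TestPcDirection:
    def _stable(self, s_vals):
        return pd.DataFrame({"S": s_vals}, index=[f"t{i}" for i in
                                                  range(len(s_vals))])

    def test_agreeing_signs_positive(self):
        loadings = np.array([[0.9], [0.8], [0.01]])
        out = selscan.pc_direction(loadings, ["t0", "t1", "t2"],
                                   self._stable([1.0, 2.0, -5.0]), top_frac=0.67)
        assert out[0] == 1

    def test_opposing_signs_negative(self):
        loadings = np.array([[0.9], [0.8], [0.01]])
        out = selscan.pc_direction(loadings, ["t0", "t1", "t2"],
                                   self._stable([-1.0, -2.0, 5.0]), top_frac=0.67)
        assert out[0] == -1

    def test_tie_unresolved(self):
        loadings = np.array([[0.9], [0.8]])
        out = selscan.pc_direction(loadings, ["t0", "t1"],
                                   self._stable([1.0, -1.0]), top_frac=1.0)
        assert out[0] == 0


class TestTraitGradients:
    def test_correlated_pair_pruned(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=100)
        traits = pd.DataFrame({
            "x": a, "y": 0.95 * a + 0.1 * rng.normal(size=100),
            "z": rng.normal(size=100),
        })
        kept = selscan.prune_correlated(traits, 0.6)
        assert len(kept) == 2 and "z" in kept

    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(11)
        traits = pd.DataFrame({"x": rng.normal(size=80),
                               "y": rng.normal(size=80)})
        zx = (traits["x"] - traits["x"].mean()) / traits["x"].std(ddof=1)
        w = 1 + 0.25 * zx
        out = selscan.trait_gradients(traits, w.to_numpy())
        assert out.loc["x", "beta"] == pytest.approx(0.25, abs=1e-10)

    def test_constant_fitness_gives_zero(self):
        rng = np.random.default_rng(12)
        traits = pd.DataFrame({"x": rng.normal(size=50),
                               "y": rng.normal(size=50)})
        out = selscan.trait_gradients(traits, np.ones(50))
        assert np.allclose(out[["beta", "gamma"]], 0.0, atol=1e-10)


class TestGoSelection:
    def _stable(self, s_vals):
        return pd.DataFrame({"S": s_vals}, index=[f"t{i}" for i in
                                                  range(len(s_vals))])

    def test_strong_term_significant_weak_term_not(self):
        rng = np.random.default_rng(13)
        s = rng.normal(0, 0.05, 300)
        s[:25] = 0.5  # one strongly selected block
        table = self._stable(s)
        terms = {
            "strong": [f"t{i}" for i in range(25)],
            "weak": [f"t{i}" for i in range(100, 130)],
        }
        out = selscan.go_selection(table, terms, seed=0)
        assert bool(out.loc["strong", "significant"])
        assert not bool(out.loc["weak", "significant"])

    def test_small_term_excluded(self):
        table = self._stable(np.linspace(-1, 1, 100))
        out = selscan.go_selection(table, {"tiny": [f"t{i}" for i in range(19)]},
                                   seed=0)
        assert "tiny" not in out.index

    def test_bootstrap_deterministic_under_seed(self):
        table = self._stable(np.linspace(-1, 1, 100))
        terms = {"a": [f"t{i}" for i in range(40)]}
        out1 = selscan.go_selection(table, terms, seed=3)
        out2 = selscan.go_selection(table, terms, seed=3)
        pd.testing.assert_frame_equal(out1, out2)
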