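"""Module preservation statistics: observed stats, permutation Z, ranks."""

import numpy as np
import pandas as pd
import pytest

from polynet.io import ExpressionMatrix, PolynetError
from polynet.preservation import (classify_preservation, median_rank,
                                  observed_stats, zsummary)
from polynet.simulate import make_correlated_block


def _expr(mat, genes=None, prefix="s"):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        mat, index=genes, columns=[f"{prefix}{j}" for j in range(mat.shape[1])]))


@pytest.fixture
def planted(rng):
    """Reference + test datasets sharing one planted 30-gene module
    (with hub structure) over 100 genes."""
    load = rng.uniform(0.82, 0.98, 30)
    ref = np.vstack([make_correlated_block(30, 20, 0.9, rng, loadings=load),
                     rng.normal(size=(70, 20))])
    test = np.vstack([make_correlated_block(30, 20, 0.9, rng, loadings=load),
                      rng.normal(size=(70, 20))])
    labels = pd.Series([1] * 30 + [0] * 70, index=[f"g{i}" for i in range(100)])
    return labels, _expr(ref), _expr(test, prefix="t")


class TestObservedStats:
    def test_self_comparison_gives_unit_connectivity_stats(self, planted):
        labels, ref, _ = planted
        obs = observed_stats(labels, ref, ref)
        assert obs.loc[1, "cor_kIM"] == pytest.approx(1.0)
        assert obs.loc[1, "cor_cor"] == pytest.approx(1.0)

    def test_uncorrelated_module_has_near_zero_density(self, rng):
        expr = _expr(rng.normal(size=(40, 30)))
        labels = pd.Series([1] * 40, index=expr.genes)
        obs = observed_stats(labels, expr, expr)
        assert abs(obs.loc[1, "meanCor"]) < 0.1

    def test_matches_brute_force_on_small_module(self, rng):
        """All four statistics recomputed by explicit double loops."""
        n = 8
        ref = _expr(rng.normal(size=(n, 12)))
        test = _expr(rng.normal(size=(n, 12)), prefix="t")
        labels = pd.Series([1] * n, index=ref.genes)
        beta = 6.0
        obs = observed_stats(labels, ref, test, beta=beta)
        R = np.array([[np.corrcoef(ref.values.iloc[i], ref.values.iloc[j])[0, 1]
                       for j in range(n)] for i in range(n)])
        T = np.array([[np.corrcoef(test.values.iloc[i], test.values.iloc[j])[0, 1]
                       for j in range(n)] for i in range(n)])
        off = ~np.eye(n, dtype=bool)
        assert obs.loc[1, "meanCor"] == pytest.approx(T[off].mean(), abs=1e-12)
        assert obs.loc[1, "meanAdj"] == pytest.approx(
            (np.abs(T) ** beta)[off].mean(), abs=1e-12)
        kim_r = [(np.abs(R[i]) ** beta).sum() - 1 for i in range(n)]
        kim_t = [(np.abs(T[i]) ** beta).sum() - 1 for i in range(n)]
        assert obs.loc[1, "cor_kIM"] == pytest.approx(
            np.corrcoef(kim_r, kim_t)[0, 1], abs=1e-10)
        iu = np.triu_indices(n, 1)
        assert obs.loc[1, "cor_cor"] == pytest.approx(
            np.corrcoef(R[iu], T[iu])[0, 1], abs=1e-10)

    def test_tiny_module_flagged_na(self, rng):
        expr = _expr(rng.normal(size=(5, 10)))
        labels = pd.Series([1, 1, 2, 2, 2], index=expr.genes)
        with pytest.warns(UserWarning, match="fewer than 3"):
            obs = observed_stats(labels, expr, expr)
        assert np.isnan(obs.loc[1, "meanCor"])


class TestMedianRank:
    def test_strongest_module_ranks_first(self):
        obs = pd.DataFrame({
            "meanCor": [0.9, 0.3, 0.1], "meanAdj": [0.8, 0.2, 0.05],
            "cor_kIM": [0.95, 0.4, 0.2], "cor_cor": [0.9, 0.5, 0.1]},
            index=[1, 2, 3])
        mr = median_rank(obs)
        assert mr.loc[1] == 1.0
        assert mr.loc[3] == 3.0

    def test_ties_get_average_rank(self):
        obs = pd.DataFrame({
            "meanCor": [0.5, 0.5], "meanAdj": [0.4, 0.4],
            "cor_kIM": [0.6, 0.6], "cor_cor": [0.3, 0.3]}, index=[1, 2])
        mr = median_rank(obs)
        assert mr.loc[1] == mr.loc[2] == 1.5

    def test_matches_sorting_oracle(self, rng):
        obs = pd.DataFrame(rng.uniform(size=(5, 4)),
                           columns=["meanCor", "meanAdj", "cor_kIM", "cor_cor"],
                           index=range(5))
        mr = median_rank(obs)
        for m in obs.index:
            ranks = []
            for c in obs.columns:
                vals = obs[c]
                rank = 1 + (vals > vals.loc[m]).sum() \
                    + 0.5 * ((vals == vals.loc[m]).sum() - 1)
                ranks.append(rank)
            assert mr.loc[m] == np.median(ranks)

    def test_needs_two_modules(self):
        with pytest.raises(PolynetError):
            median_rank(pd.DataFrame({"meanCor": [1.0], "meanAdj": [1.0],
                                      "cor_kIM": [1.0], "cor_cor": [1.0]}))


class TestZsummary:
    def test_preserved_module_scores_high(self, planted):
        labels, ref, test = planted
        res = zsummary(labels, ref, test, n_perm=30, seed=0)
        assert res.table.loc[1, "Zsummary"] > 5

    def test_destroyed_signal_scores_low(self, planted, rng):
        labels, ref, test = planted
        shuffled = test.values.to_numpy().copy()
        for row in shuffled:
            rng.shuffle(row)
        test2 = ExpressionMatrix(pd.DataFrame(shuffled, index=test.genes,
                                              columns=test.samples))
        res = zsummary(labels, ref, test2, n_perm=30, seed=0)
        assert res.table.loc[1, "Zsummary"] < 2

    def test_deterministic_under_seed(self, planted):
        labels, ref, test = planted
        r1 = zsummary(labels, ref, test, n_perm=25, seed=42)
        r2 = zsummary(labels, ref, test, n_perm=25, seed=42)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_rejects_too_few_permutations(self, planted):
        labels, ref, test = planted
        with pytest.raises(PolynetError):
            zsummary(labels, ref, test, n_perm=5)

    def test_zsummary_grows_with_module_size(self, rng):
        """Same per-gene signal strength, bigger module -> bigger Zsummary.

        Uses a moderate-strength module and soft threshold: with a
        near-perfect module the small-module permutation null degenerates
        (null sd near 0) and the Z scale saturates."""
        out = {}
        n_bg = 500  # background dominates so permuted null sets stay mixed
        for size, label in ((25, "small"), (90, "large")):
            load = rng.uniform(0.42, 0.58, size)
            ref = np.vstack([make_correlated_block(size, 20, 0.5, rng, loadings=load),
                             rng.normal(size=(n_bg, 20))])
            test = np.vstack([make_correlated_block(size, 20, 0.5, rng, loadings=load),
                              rng.normal(size=(n_bg, 20))])
            genes = [f"g{i}" for i in range(size + n_bg)]
            labels = pd.Series([1] * size + [0] * n_bg, index=genes)
            res = zsummary(labels, _expr(ref, genes=genes),
                           _expr(test, genes=genes, prefix="t"),
                           n_perm=60, seed=1, beta=6.0)
            out[label] = res.table.loc[1, "Zsummary"]
        assert out["large"] > out["small"]


class TestClassify:
    @pytest.mark.parametrize("z,expected", [
        (10.5, "strong"), (10.0, "moderate"), (2.0, "moderate"),
        (1.9, "none"), (-3.0, "none"),
    ])
    def test_thresholds(self, z, expected):
        assert classify_preservation(pd.Series([z])).iloc[0] == expected
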