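"""Coexpression network construction: correlation, adjacency, TOM,
module detection, eigengenes, kME, and the eigengene-condition ANOVA."""

import numpy as np
import pandas as pd
import pytest

from polynet.io import ExpressionMatrix, PolynetError
from polynet.network import (NetworkParams, adjacency, correlation_matrix,
                             detect_modules, kme, me_condition_anova,
                             module_eigengenes, pick_beta, scale_free_fit, tom)
from polynet.simulate import make_correlated_block


def _expr(mat, prefix="g"):
    mat = np.asarray(mat, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        mat, index=[f"{prefix}{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])]))


def _block_expr(rng, sizes, n_samples=24, rho=0.9, n_background=0):
    blocks = [make_correlated_block(s, n_samples, rho, rng) for s in sizes]
    if n_background:
        blocks.append(rng.normal(size=(n_background, n_samples)))
    return _expr(np.vstack(blocks))


class TestCorrelation:
    def test_matches_double_loop(self, rng):
        expr = _expr(rng.normal(size=(5, 8)))
        cor = correlation_matrix(expr)
        for i in range(5):
            for j in range(5):
                x = expr.values.iloc[i]
                y = expr.values.iloc[j]
                oracle = np.corrcoef(x, y)[0, 1]
                assert cor.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_duplicate_and_negated_gene(self, rng):
        base = rng.normal(size=8)
        expr = _expr(np.vstack([base, base, -base]))
        cor = correlation_matrix(expr)
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_rejected(self, rng):
        mat = rng.normal(size=(3, 6))
        mat[1] = 5.0
        with pytest.raises(PolynetError, match="g1"):
            correlation_matrix(_expr(mat))


class TestAdjacency:
    def test_powers(self):
        cor = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        adj = adjacency(cor, beta=12)
        assert adj.loc["a", "b"] == pytest.approx(0.9 ** 12)
        assert adj.loc["a", "a"] == 1.0

    def test_unsigned(self):
        cor = pd.DataFrame([[1.0, -0.9], [-0.9, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        adj = adjacency(cor, beta=12)
        assert adj.loc["a", "b"] == pytest.approx(0.9 ** 12)


class TestScaleFree:
    def test_power_law_degrees_fit_well(self):
        # hub-and-spoke-like adjacency: a_ij = c_i c_j with power-law c
        rng = np.random.default_rng(0)
        c = (1.0 / rng.uniform(0.05, 1.0, size=300)) ** 0.8
        c = np.sqrt(c / c.max())
        a = np.outer(c, c)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=range(300), columns=range(300))
        assert scale_free_fit(adj) > 0.8

    def test_uniform_connectivity_fits_poorly(self, rng):
        n = 100
        a = np.full((n, n), 0.3) + rng.normal(0, 1e-3, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=range(n), columns=range(n))
        assert scale_free_fit(adj) < 0.5

    def test_matches_independent_regression(self, rng):
        import scipy.stats
        a = np.abs(rng.normal(0.2, 0.1, size=(60, 60)))
        a = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=range(60), columns=range(60))
        fit = scale_free_fit(adj, n_bins=10)
        # oracle: same binning rule, independent regression
        k = a.sum(axis=0) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        freq = np.bincount(which, minlength=10)
        keep = freq > 0
        means = np.array([k[which == b].mean() for b in range(10) if freq[b] > 0])
        dens = freq[keep] / freq.sum()
        slope, _, r, _, _ = scipy.stats.linregress(np.log10(means), np.log10(dens))
        assert fit == pytest.approx(r ** 2 * np.sign(-slope), abs=1e-10)


class TestTOM:
    def test_three_gene_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        t = tom(adj)
        # k = 1 each, l = 0.25, TOM = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert t.loc["a", "b"] == pytest.approx(0.5)
        assert np.allclose(np.diag(t), 1.0)

    def test_disconnected_genes_zero_overlap(self):
        a = np.eye(4)
        adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
        t = tom(adj)
        assert t.loc["a", "b"] == 0.0

    def test_matches_brute_force(self, rng):
        n = 15
        a = np.abs(rng.normal(0.3, 0.2, size=(n, n)))
        a = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=range(n), columns=range(n))
        t = tom(adj).to_numpy()
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert t[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                oracle = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(oracle, abs=1e-12)


class TestDetectModules:
    def test_two_clean_blocks(self, rng):
        expr = _block_expr(rng, [60, 60], rho=0.9)
        cor = correlation_matrix(expr)
        t = tom(adjacency(cor, 12))
        result = detect_modules(t, NetworkParams(), expr=expr)
        labels = result.labels
        assert sorted(labels.unique()) == [1, 2]
        assert labels.iloc[:60].nunique() == 1
        assert labels.iloc[60:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[60]

    def test_permutation_equivariance(self, rng):
        expr = _block_expr(rng, [50, 35], rho=0.9, n_background=20)
        cor = correlation_matrix(expr)
        t = tom(adjacency(cor, 12))
        labels = detect_modules(t, NetworkParams(min_module_size=20), expr=expr).labels
        perm = rng.permutation(len(labels))
        expr_p = ExpressionMatrix(expr.values.iloc[perm])
        t_p = t.iloc[perm, perm]
        labels_p = detect_modules(t_p, NetworkParams(min_module_size=20),
                                  expr=expr_p).labels
        assert labels_p.equals(labels.iloc[perm])

    def test_duplicate_latent_modules_merged(self, rng):
        shared = rng.normal(size=24)
        b1 = make_correlated_block(40, 24, 0.9, rng, shared=shared)
        b2 = make_correlated_block(40, 24, 0.9, rng, shared=shared)
        expr = _expr(np.vstack([b1, b2]))
        cor = correlation_matrix(expr)
        t = tom(adjacency(cor, 12))
        result = detect_modules(t, NetworkParams(), expr=expr)
        assert len([m for m in result.labels.unique() if m != 0]) == 1

    def test_small_clusters_unassigned(self, rng):
        expr = _block_expr(rng, [10], rho=0.95, n_background=40)
        cor = correlation_matrix(expr)
        t = tom(adjacency(cor, 12))
        with pytest.warns(UserWarning):
            result = detect_modules(t, NetworkParams(min_module_size=30), expr=expr)
        assert result.labels.max() == 0


class TestEigengenes:
    def test_identical_genes_give_unit_kme(self, rng):
        base = rng.normal(size=12)
        noise = rng.normal(0, 1e-6, size=(5, 12))
        expr = _expr(base[None, :] + noise)
        labels = pd.Series(1, index=expr.genes)
        me = module_eigengenes(expr, labels)
        k = kme(expr, me)
        assert np.allclose(k[1], 1.0, atol=1e-4)
        assert np.linalg.norm(me.values.loc[1]) == pytest.approx(1.0)

    def test_orientation_convention(self, rng):
        expr = _expr(make_correlated_block(20, 12, 0.9, rng))
        labels = pd.Series(1, index=expr.genes)
        me = module_eigengenes(expr, labels)
        k = kme(expr, me)
        assert k[1].mean() > 0
        flipped = ExpressionMatrix(-expr.values)
        me_f = module_eigengenes(flipped, labels)
        k_f = kme(flipped, me_f)
        assert k_f[1].mean() > 0

    def test_variance_explained_matches_svd(self, rng):
        expr = _expr(rng.normal(size=(50, 12)))
        labels = pd.Series(1, index=expr.genes)
        me = module_eigengenes(expr, labels)
        z = expr.values.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        s = np.linalg.svd(z, compute_uv=False)
        assert me.var_explained.loc[1] == pytest.approx(s[0] ** 2 / (s ** 2).sum(),
                                                        abs=1e-10)

    def test_kme_matches_looped_correlation(self, rng):
        expr = _expr(rng.normal(size=(15, 10)))
        labels = pd.Series([1] * 8 + [2] * 7, index=expr.genes)
        me = module_eigengenes(expr, labels)
        k = kme(expr, me)
        for g in expr.genes:
            for m in me.modules:
                oracle = np.corrcoef(expr.values.loc[g], me.values.loc[m])[0, 1]
                assert k.loc[g, m] == pytest.approx(oracle, abs=1e-12)


class TestMEAnova:
    def _eigengenes(self, profile, samples):
        values = pd.DataFrame([profile], index=pd.Index([1], name="module"),
                              columns=samples)
        from polynet.network import EigengeneMatrix
        return EigengeneMatrix(values=values,
                               var_explained=pd.Series([1.0], index=values.index))

    def test_stage_driven_profile(self):
        from polynet.simulate import SimParams, make_sample_meta
        meta = make_sample_meta(SimParams())
        profile = meta["stage_dpa"].to_numpy(float)
        res = me_condition_anova(self._eigengenes(profile, meta.index), meta)
        assert res.loc[1, "p_stage"] < 1e-10
        assert res.loc[1, "significant"]

    def test_f_statistic_matches_hand_computed(self, rng):
        from polynet.simulate import SimParams, make_sample_meta
        meta = make_sample_meta(SimParams())
        y = rng.normal(size=24)
        res = me_condition_anova(self._eigengenes(y, meta.index), meta)
        # balanced two-way ANOVA sums of squares by hand
        import scipy.stats
        df = pd.DataFrame({"y": y, "g": meta["group"].to_numpy(),
                           "t": meta["stage_dpa"].to_numpy()})
        grand = df["y"].mean()
        ss_g = sum(len(sub) * (sub["y"].mean() - grand) ** 2
                   for _, sub in df.groupby("g"))
        ss_t = sum(len(sub) * (sub["y"].mean() - grand) ** 2
                   for _, sub in df.groupby("t"))
        fitted = (df.groupby("g")["y"].transform("mean")
                  + df.groupby("t")["y"].transform("mean") - grand)
        ss_res = ((df["y"] - fitted) ** 2).sum()
        df_res = 24 - 1 - 1 - 3
        f_g = (ss_g / 1) / (ss_res / df_res)
        f_t = (ss_t / 3) / (ss_res / df_res)
        assert res.loc[1, "p_group"] == pytest.approx(
            scipy.stats.f.sf(f_g, 1, df_res), abs=1e-10)
        assert res.loc[1, "p_stage"] == pytest.approx(
            scipy.stats.f.sf(f_t, 3, df_res), abs=1e-10)


def test_pick_beta_prefers_smallest_reaching_target(rng):
    expr = _block_expr(rng, [40, 40], rho=0.9, n_background=120)
    cor = correlation_matrix(expr)
    beta, table = pick_beta(cor, candidates=(2, 4, 6, 8, 10, 12), target=0.8)
    assert beta in {2, 4, 6, 8, 10, 12}
    reached = table[table["fit_index"] >= 0.8]
    if len(reached):
        assert beta == reached["beta"].iloc[0]
    else:
        assert beta == table.loc[table["fit_index"].idxmax(), "beta"]
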