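"""Differential correlation between two expression datasets.

For every unordered gene pair, the Pearson correlation is computed in each
dataset (e.g., wild vs. domesticated libraries) and the difference tested
with Fisher's z: z_k = atanh(r_k), statistic = (z1 - z2) /
sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal P.  Pair-level significance
uses a local false discovery rate by default (empirical-Bayes two-group
model with a theoretical N(0,1) null), with Benjamini-Hochberg as the
simpler alternative.

Genes carrying significantly more differentially correlated (DC) pairs
than expected are then flagged: with k significant pairs among n tested
partners and a global significant-pair fraction p0, the gene-level P is
the binomial upper tail Pr[X >= k], X ~ Binomial(n, p0), BH-corrected
across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from sklearn.isotonic import IsotonicRegression

from .io import ExpressionMatrix, PolynetError
from .diffexpr import bh_adjust

__all__ = [
    "DCPairResult",
    "DCGeneResult",
    "fisher_z_test",
    "dc_pairs",
    "local_fdr",
    "dc_genes",
]

MIN_TESTS_FOR_LFDR = 100
R_CLIP = 1.0 - 1e-12


@dataclass
class DCPairResult:
    """Per-pair table: gene_i, gene_j, r_wild, r_dom, stat, pvalue,
    lfdr or padj, significant."""

    table: pd.DataFrame
    method: str
    threshold: float
    n_wild: int
    n_dom: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


@dataclass
class DCGeneResult:
    """Per-gene table: k, n, p0, pvalue, padj, dc_flag."""

    table: pd.DataFrame
    p0: float


def fisher_z_test(r1, n1: int, r2, n2: int):
    """Fisher z-test for a difference between two correlations.

    Accepts scalars or arrays; |r| = 1 is clipped just inside the open
    interval (flagged with a warning).  Returns (statistic, two-sided P).
    """
    if n1 < 4 or n2 < 4:
        raise PolynetError("Fisher z-test needs at least 4 samples per dataset")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if (np.abs(r1) >= 1).any() or (np.abs(r2) >= 1).any():
        warnings.warn("correlations at |r| = 1 clipped for the z-transform")
    r1 = np.clip(r1, -R_CLIP, R_CLIP)
    r2 = np.clip(r2, -R_CLIP, R_CLIP)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    stat = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


def dc_pairs(expr_wild: ExpressionMatrix, expr_dom: ExpressionMatrix,
             threshold: float = 0.05, method: str = "lfdr") -> DCPairResult:
    """Test all unordered gene pairs for wild-vs-domesticated correlation
    change."""
    genes = expr_wild.genes
    if not genes.equals(expr_dom.genes):
        raise PolynetError("wild and domesticated datasets must share the gene universe")
    n1 = expr_wild.values.shape[1]
    n2 = expr_dom.values.shape[1]
    if n1 < 4 or n2 < 4:
        raise PolynetError("need at least 4 samples per dataset")
    rw = np.clip(np.corrcoef(expr_wild.values.to_numpy(float)), -1, 1)
    rd = np.clip(np.corrcoef(expr_dom.values.to_numpy(float)), -1, 1)
    iu = np.triu_indices(len(genes), k=1)
    r1 = rw[iu]
    r2 = rd[iu]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = fisher_z_test(r1, n1, r2, n2)
    table = pd.DataFrame({
        "gene_i": genes.to_numpy()[iu[0]],
        "gene_j": genes.to_numpy()[iu[1]],
        "r_wild": r1,
        "r_dom": r2,
        "stat": stat,
        "pvalue": p,
    })
    if method == "lfdr":
        table["lfdr"] = local_fdr(table["stat"].to_numpy())
        table["significant"] = table["lfdr"] < threshold
    elif method == "bh":
        table["padj"] = bh_adjust(table["pvalue"]).to_numpy()
        table["significant"] = table["padj"] < threshold
    else:
        raise PolynetError(f"unknown method {method!r}; use 'lfdr' or 'bh'")
    return DCPairResult(table=table, method=method, threshold=threshold,
                        n_wild=n1, n_dom=n2)


def local_fdr(z: np.ndarray) -> np.ndarray:
    """Local FDR for z-scores under a two-group model with theoretical
    N(0,1) null.

    The marginal density f is a smoothed histogram; pi0 is estimated from
    the density ratio at the center of the distribution; lfdr(z) =
    clip(pi0 * phi(z) / f(z), 0, 1), made monotone non-increasing in |z|
    by isotonic regression.  Falls back to BH-adjusted P values when fewer
    than 100 tests are supplied.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < MIN_TESTS_FOR_LFDR:
        warnings.warn("fewer than 100 tests; falling back to BH adjustment")
        p = 2.0 * scipy.stats.norm.sf(np.abs(z))
        return bh_adjust(pd.Series(p)).to_numpy()
    lo, hi = z.min() - 0.5, z.max() + 0.5
    n_bins = min(max(51, n // 200), 501)
    counts, edges = np.histogram(z, bins=n_bins, range=(lo, hi))
    width = edges[1] - edges[0]
    smooth = scipy.ndimage.gaussian_filter1d(counts.astype(float), sigma=2.0)
    dens = smooth / (smooth.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    floor = 1.0 / (n * width * 10.0)
    f = np.maximum(np.interp(z, centers, dens), floor)
    f0 = scipy.stats.norm.pdf(z)
    f_at_0 = max(np.interp(0.0, centers, dens), floor)
    pi0 = min(1.0, f_at_0 / scipy.stats.norm.pdf(0.0))
    raw = np.clip(pi0 * f0 / f, 0.0, 1.0)
    # enforce monotone non-increasing lfdr in |z|
    order = np.argsort(np.abs(z))
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(np.abs(z)[order], raw[order])
    out = np.empty(n)
    out[order] = fitted
    return out


def dc_genes(pairs: DCPairResult, alpha: float = 0.05) -> DCGeneResult:
    """Binomial test for genes enriched in significant DC pairs."""
    tab = pairs.table
    n_pairs_total = len(tab)
    n_sig_total = int(tab["significant"].sum())
    p0 = n_sig_total / n_pairs_total if n_pairs_total else 0.0
    genes = pd.unique(np.concatenate([tab["gene_i"].to_numpy(),
                                      tab["gene_j"].to_numpy()]))
    k = pd.Series(0, index=pd.Index(genes, name="gene"))
    n = pd.Series(0, index=k.index)
    for col in ("gene_i", "gene_j"):
        n = n.add(tab[col].value_counts(), fill_value=0)
        k = k.add(tab.loc[tab["significant"], col].value_counts(), fill_value=0)
    k = k.astype(int)
    n = n.astype(int)
    if p0 == 0.0:
        pvalue = pd.Series(1.0, index=k.index)
        inconsistent = k > 0
        if inconsistent.any():
            warnings.warn("p0 = 0 but some genes have significant pairs")
    else:
        pvalue = pd.Series(scipy.stats.binom.sf(k.to_numpy() - 1, n.to_numpy(), p0),
                           index=k.index)
    padj = bh_adjust(pvalue)
    table = pd.DataFrame({"k": k, "n": n, "p0": p0, "pvalue": pvalue,
                          "padj": padj, "dc_flag": padj < alpha})
    return DCGeneResult(table=table, p0=p0)
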