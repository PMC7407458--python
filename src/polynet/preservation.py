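"""Module preservation between a reference and a test expression dataset.

Asks whether modules defined on a reference network keep their density and
connectivity patterns in an independent test dataset.  Four observed
statistics per module (all computed from expression alone):

* meanCor  — mean off-diagonal intramodule correlation in the test data
  (density);
* meanAdj  — mean intramodule soft-threshold adjacency in the test data
  (density);
* cor_kIM  — correlation between genes' intramodular connectivity in the
  reference vs. the test data (connectivity);
* cor_cor  — correlation between the vectorized intramodule correlation
  matrices of reference and test (connectivity).

A permutation null (module labels shuffled among genes, sizes preserved)
standardizes each statistic into a Z; Zdensity and Zconnectivity are the
medians of their two Zs and Zsummary their mean.  Conventional reading:
Zsummary > 10 strong preservation, 2–10 weak to moderate, < 2 none.
medianRank compares modules to each other (1 = most preserved) and, unlike
Zsummary, is insensitive to module size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PolynetError

__all__ = [
    "PreservationResult",
    "observed_stats",
    "zsummary",
    "median_rank",
    "classify_preservation",
]

STAT_NAMES = ("meanCor", "meanAdj", "cor_kIM", "cor_cor")
DENSITY_STATS = ("meanCor", "meanAdj")
CONNECTIVITY_STATS = ("cor_kIM", "cor_cor")


@dataclass
class PreservationResult:
    """Per-module observed statistics, Z scores, Zsummary, medianRank."""

    table: pd.DataFrame
    n_permutations: int
    seed: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats(idx: np.ndarray, cor_ref: np.ndarray, cor_test: np.ndarray,
                  beta: float) -> dict[str, float]:
    sub_ref = cor_ref[np.ix_(idx, idx)]
    sub_test = cor_test[np.ix_(idx, idx)]
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    adj_ref = np.abs(sub_ref) ** beta
    adj_test = np.abs(sub_test) ** beta
    kim_ref = adj_ref.sum(axis=0) - 1.0
    kim_test = adj_test.sum(axis=0) - 1.0
    iu = np.triu_indices(n, k=1)
    return {
        "meanCor": float(sub_test[off].mean()),
        "meanAdj": float(adj_test[off].mean()),
        "cor_kIM": _pearson(kim_ref, kim_test),
        "cor_cor": _pearson(sub_ref[iu], sub_test[iu]),
    }


def _aligned_correlations(ref_labels: pd.Series, ref_expr: ExpressionMatrix,
                          test_expr: ExpressionMatrix):
    genes = ref_labels.index.intersection(ref_expr.genes).intersection(test_expr.genes)
    if len(genes) == 0:
        raise PolynetError("no shared genes between labels, reference and test data")
    labels = ref_labels.loc[genes]
    Xr = ref_expr.values.loc[genes].to_numpy(float)
    Xt = test_expr.values.loc[genes].to_numpy(float)
    cor_ref = np.corrcoef(Xr)
    cor_test = np.corrcoef(Xt)
    cor_ref = np.nan_to_num(np.clip(cor_ref, -1, 1))
    cor_test = np.nan_to_num(np.clip(cor_test, -1, 1))
    return genes, labels, cor_ref, cor_test


def observed_stats(ref_labels: pd.Series, ref_expr: ExpressionMatrix,
                   test_expr: ExpressionMatrix, beta: float = 12.0) -> pd.DataFrame:
    """Observed preservation statistics per module (label 0 excluded)."""
    genes, labels, cor_ref, cor_test = _aligned_correlations(
        ref_labels, ref_expr, test_expr)
    rows = {}
    lab = labels.to_numpy()
    for m in sorted(set(lab) - {0}):
        idx = np.flatnonzero(lab == m)
        if len(idx) < 3:
            warnings.warn(f"module {m} has fewer than 3 genes in the test data; NA stats")
            rows[m] = {s: np.nan for s in STAT_NAMES} | {"size": len(idx)}
            continue
        rows[m] = _module_stats(idx, cor_ref, cor_test, beta) | {"size": len(idx)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def median_rank(observed: pd.DataFrame) -> pd.Series:
    """Per-module medianRank: each statistic ranked across modules with
    rank 1 the most preserved (largest value, ties averaged); the module's
    medianRank is the median of its four statistic ranks."""
    if len(observed) < 2:
        raise PolynetError("medianRank needs at least 2 modules")
    ranks = pd.DataFrame(index=observed.index)
    for s in STAT_NAMES:
        ranks[s] = observed[s].rank(ascending=False, method="average")
    return ranks.median(axis=1).rename("medianRank")


def zsummary(ref_labels: pd.Series, ref_expr: ExpressionMatrix,
             test_expr: ExpressionMatrix, n_perm: int = 100, seed: int = 0,
             beta: float = 12.0) -> PreservationResult:
    """Permutation Z statistics and Zsummary per module.

    The null shuffles module labels among all genes (module sizes kept),
    recomputing the four statistics per permutation.  Z = (obs - null
    mean) / null sd; a zero null sd yields +/-inf, flagged by the
    ``degenerate_null`` column.
    """
    if n_perm < 20:
        raise PolynetError("n_perm must be >= 20 for usable null moments")
    genes, labels, cor_ref, cor_test = _aligned_correlations(
        ref_labels, ref_expr, test_expr)
    lab = labels.to_numpy()
    modules = sorted(set(lab) - {0})
    obs = observed_stats(ref_labels, ref_expr, test_expr, beta)

    rng = np.random.default_rng(seed)
    null = {m: {s: [] for s in STAT_NAMES} for m in modules}
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        for m in modules:
            idx = np.flatnonzero(perm == m)
            if len(idx) < 3:
                continue
            stats = _module_stats(idx, cor_ref, cor_test, beta)
            for s in STAT_NAMES:
                null[m][s].append(stats[s])

    table = obs.copy()
    for s in STAT_NAMES:
        zcol = []
        for m in modules:
            draws = np.asarray(null[m][s], dtype=float)
            draws = draws[np.isfinite(draws)]
            if len(draws) < 2 or not np.isfinite(obs.loc[m, s]):
                zcol.append(np.nan)
                continue
            sd = draws.std(ddof=1)
            if sd == 0:
                zcol.append(np.inf if obs.loc[m, s] > draws.mean() else -np.inf)
            else:
                zcol.append((obs.loc[m, s] - draws.mean()) / sd)
        table[f"Z_{s}"] = zcol
    zd = table[[f"Z_{s}" for s in DENSITY_STATS]].median(axis=1)
    zc = table[[f"Z_{s}" for s in CONNECTIVITY_STATS]].median(axis=1)
    table["Zdensity"] = zd
    table["Zconnectivity"] = zc
    table["Zsummary"] = (zd + zc) / 2.0
    table["degenerate_null"] = ~np.isfinite(
        table[[f"Z_{s}" for s in STAT_NAMES]].to_numpy(float)).all(axis=1)
    if len(table) >= 2:
        table["medianRank"] = median_rank(obs)
    else:
        table["medianRank"] = 1.0
    table["class"] = classify_preservation(table["Zsummary"])
    return PreservationResult(table=table, n_permutations=n_perm, seed=seed)


def classify_preservation(zsummary_values: pd.Series) -> pd.Series:
    """strong: Zsummary > 10; moderate: 2 <= Zsummary <= 10 (closed
    boundaries); none: Zsummary < 2."""
    z = pd.Series(zsummary_values)
    out = pd.Series("none", index=z.index, name="class")
    out[z >= 2] = "moderate"
    out[z > 10] = "strong"
    out[z.isna()] = "NA"
    return out
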