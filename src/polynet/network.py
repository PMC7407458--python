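"""Weighted gene coexpression network construction.

Pipeline: Pearson correlation between gene expression profiles -> unsigned
soft-threshold adjacency |r|^beta (beta = 12 by default, with a scale-free
fit index to guide the choice) -> topological overlap matrix (TOM) ->
average-linkage hierarchical clustering of 1 - TOM with a static dendrogram
cut, a minimum module size, merging of modules with similar eigengenes, and
kME-based rescue of unassigned genes -> module eigengenes (first principal
component of the scaled module expression) and kME (gene-eigengene
correlation, a.k.a. module membership).

Module labels are integers renumbered by descending size; 0 means
unassigned (the "grey" module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .io import ExpressionMatrix, PolynetError

__all__ = [
    "NetworkParams",
    "ModuleAssignment",
    "EigengeneMatrix",
    "NetworkResult",
    "correlation_matrix",
    "adjacency",
    "scale_free_fit",
    "pick_beta",
    "tom",
    "detect_modules",
    "module_eigengenes",
    "kme",
    "me_condition_anova",
    "build_network",
]


@dataclass(frozen=True)
class NetworkParams:
    beta: float = 12.0
    min_module_size: int = 30
    merge_height: float = 0.15
    cut_height_frac: float = 0.99
    scale_free_target: float = 0.8
    kme_reassign_threshold: float = 0.7
    kme_min_stay: float = 0.3

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise PolynetError("beta must be >= 1")
        for name in ("merge_height", "cut_height_frac", "scale_free_target"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PolynetError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class ModuleAssignment:
    """Gene -> integer module label (0 = unassigned), with sizes and the
    dendrogram linkage record."""

    labels: pd.Series
    linkage: np.ndarray | None = None

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)


@dataclass
class EigengeneMatrix:
    """Module eigengenes: modules x samples, each row the unit-norm first
    principal component of the module's scaled expression, oriented so the
    mean correlation with member genes is positive."""

    values: pd.DataFrame
    var_explained: pd.Series

    @property
    def modules(self) -> list[int]:
        return list(self.values.index)


@dataclass
class NetworkResult:
    params: NetworkParams
    expr: ExpressionMatrix
    assignment: ModuleAssignment
    eigengenes: EigengeneMatrix
    kme: pd.DataFrame
    scale_free_index: float


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlations of gene expression profiles."""
    X = expr.values.to_numpy(float)
    if X.shape[1] < 3:
        raise PolynetError("need at least 3 samples for correlations")
    sd = X.std(axis=1)
    dead = expr.genes[sd == 0]
    if len(dead):
        raise PolynetError(f"zero-variance genes present: {list(dead[:5])}"
                           f"{' ...' if len(dead) > 5 else ''}")
    cor = np.corrcoef(X)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.genes, columns=expr.genes)


def adjacency(cor: pd.DataFrame, beta: float = 12.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor_ij|^beta, diagonal 1."""
    a = np.abs(cor.to_numpy(float)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) against log10 k over binned connectivities.

    Returns R^2 * sign(-slope): a value near +1 means a good decreasing
    power-law fit (scale-free-like topology)."""
    a = adj.to_numpy(float)
    k = a.sum(axis=0) - np.diag(a)
    k = k[k > 0]
    while n_bins >= 2:
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        freq = np.bincount(which, minlength=n_bins)
        keep = freq > 0
        if keep.sum() >= 3:
            break
        warnings.warn(f"degenerate connectivity binning; reducing bins to {n_bins - 1}")
        n_bins -= 1
    means = np.array([k[which == b].mean() for b in range(n_bins) if freq[b] > 0])
    dens = freq[keep] / freq.sum()
    slope, _, r, _, _ = scipy.stats.linregress(np.log10(means), np.log10(dens))
    return float(r ** 2 * np.sign(-slope))


def pick_beta(cor: pd.DataFrame, candidates=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
              target: float = 0.8) -> tuple[float, pd.DataFrame]:
    """Smallest candidate power whose scale-free fit index reaches the
    target, else the power with the highest fit index achieved."""
    rows = []
    for b in candidates:
        fit = scale_free_fit(adjacency(cor, b))
        rows.append({"beta": b, "fit_index": fit})
        if fit >= target:
            break
    table = pd.DataFrame(rows)
    reached = table[table["fit_index"] >= target]
    best = reached.iloc[0] if len(reached) else table.loc[table["fit_index"].idxmax()]
    return float(best["beta"]), table


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij)
    with l_ij the shared-neighbor adjacency product sum and k the
    connectivity excluding self; TOM_ii = 1."""
    a = adj.to_numpy(float)
    if not np.allclose(a, a.T):
        raise PolynetError("adjacency must be symmetric")
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # noqa: E741 - standard symbol
    k = a.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (l + a) / (kmin + 1.0 - a)
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K by descending size (ties: old label order)."""
    out = np.zeros_like(labels)
    nonzero = [m for m in np.unique(labels) if m != 0]
    sizes = {m: (labels == m).sum() for m in nonzero}
    ordered = sorted(nonzero, key=lambda m: (-sizes[m], m))
    for new, old in enumerate(ordered, start=1):
        out[labels == old] = new
    return out


def detect_modules(tomatrix: pd.DataFrame, params: NetworkParams = NetworkParams(),
                   expr: ExpressionMatrix | None = None) -> ModuleAssignment:
    """Cluster 1 - TOM by average linkage and cut into modules.

    Static cut at cut_height_frac x the dendrogram's maximum merge height;
    clusters below min_module_size are unassigned (label 0).  If ``expr``
    is given, modules whose eigengene dissimilarity is below merge_height
    are merged, and unassigned genes with kME above the rescue threshold
    join their best module.  Labels are renumbered by descending size.
    """
    genes = tomatrix.index
    dissim = 1.0 - tomatrix.to_numpy(float)
    np.fill_diagonal(dissim, 0.0)
    condensed = ssd.squareform(dissim, checks=False)
    Z = sch.linkage(condensed, method="average")
    cut = params.cut_height_frac * Z[:, 2].max() if len(Z) else 0.0
    raw = sch.fcluster(Z, t=cut, criterion="distance")
    labels = raw.astype(int)
    for m in np.unique(labels):
        if (labels == m).sum() < params.min_module_size:
            labels[labels == m] = 0
    labels = _renumber_by_size(labels)
    if labels.max() == 0:
        warnings.warn("no module passed the minimum size filter; all genes unassigned")

    series = pd.Series(labels, index=genes, name="module")
    if expr is not None and labels.max() > 1:
        series = _merge_similar_modules(series, expr, params)
    if expr is not None and series.max() > 0:
        series = _drop_weak_members(series, expr, params)
    if expr is not None and (series == 0).any() and series.max() > 0:
        series = _rescue_unassigned(series, expr, params)
    series = pd.Series(_renumber_by_size(series.to_numpy()), index=genes, name="module")
    return ModuleAssignment(labels=series, linkage=Z)


def _merge_similar_modules(labels: pd.Series, expr: ExpressionMatrix,
                           params: NetworkParams) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            return labels
        me = module_eigengenes(expr, labels)
        M = me.values.to_numpy(float)
        cor = np.corrcoef(M)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= params.merge_height:
            return labels
        a, b = me.modules[i], me.modules[j]
        labels[labels == max(a, b)] = min(a, b)


def _drop_weak_members(labels: pd.Series, expr: ExpressionMatrix,
                       params: NetworkParams) -> pd.Series:
    """Unassign genes whose membership (|kME| to their own module) falls
    below the stay threshold, mirroring WGCNA's minKMEtoStay cleanup."""
    labels = labels.copy()
    me = module_eigengenes(expr, labels)
    k = kme(expr, me)
    for m in me.modules:
        members = labels.index[labels == m]
        weak = members[np.abs(k.loc[members, m].to_numpy()) < params.kme_min_stay]
        labels.loc[weak] = 0
    return labels


def _rescue_unassigned(labels: pd.Series, expr: ExpressionMatrix,
                       params: NetworkParams) -> pd.Series:
    labels = labels.copy()
    me = module_eigengenes(expr, labels)
    k = kme(expr, me)
    grey = labels.index[labels == 0]
    sub = k.loc[grey]
    best = sub.idxmax(axis=1)
    best_val = sub.max(axis=1)
    joiners = grey[best_val.to_numpy() > params.kme_reassign_threshold]
    labels.loc[joiners] = best.loc[joiners].astype(int)
    return labels


def module_eigengenes(expr: ExpressionMatrix, labels: pd.Series) -> EigengeneMatrix:
    """First principal component of each module's standardized expression,
    oriented for positive mean member correlation."""
    rows, ve = [], []
    mods = sorted(m for m in pd.unique(labels) if m != 0)
    X = expr.values
    out_mods = []
    for m in mods:
        genes = labels.index[labels == m]
        sub = X.loc[genes].to_numpy(float)
        sd = sub.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        if ok.sum() < 2:
            warnings.warn(f"module {m} has fewer than 2 non-constant genes; excluded")
            continue
        sub = sub[ok]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[ok]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        member_cor = (z / np.linalg.norm(z, axis=1, keepdims=True)) @ (me / np.linalg.norm(me))
        if member_cor.mean() < 0:
            me = -me
        rows.append(me)
        ve.append(s[0] ** 2 / (s ** 2).sum())
        out_mods.append(m)
    values = pd.DataFrame(rows, index=pd.Index(out_mods, name="module"),
                          columns=expr.samples)
    return EigengeneMatrix(values=values,
                           var_explained=pd.Series(ve, index=values.index,
                                                   name="var_explained"))


def kme(expr: ExpressionMatrix, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Gene x module Pearson correlations with the module eigengenes."""
    X = expr.values.to_numpy(float)
    M = eigengenes.values.to_numpy(float)
    if X.shape[1] != M.shape[1]:
        raise PolynetError("expression and eigengenes have different sample sets")
    Xz = X - X.mean(axis=1, keepdims=True)
    Mz = M - M.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xz, axis=1, keepdims=True)
    mn = np.linalg.norm(Mz, axis=1, keepdims=True)
    xn[xn == 0] = np.inf
    mn[mn == 0] = np.inf
    k = (Xz / xn) @ (Mz / mn).T
    return pd.DataFrame(np.clip(k, -1.0, 1.0), index=expr.genes,
                        columns=eigengenes.values.index)


def me_condition_anova(eigengenes: EigengeneMatrix, sample_meta: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA of each module eigengene on domestication group and
    developmental stage (categorical); F-test P per factor."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    meta = sample_meta.loc[eigengenes.values.columns]
    rows = []
    for m in eigengenes.modules:
        df = pd.DataFrame({
            "me": eigengenes.values.loc[m].to_numpy(float),
            "group": meta["group"].to_numpy(),
            "stage": meta["stage_dpa"].astype(str).to_numpy(),
        })
        if df["me"].std() == 0:
            rows.append({"module": m, "p_group": np.nan, "p_stage": np.nan,
                         "significant": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ols("me ~ C(group) + C(stage)", data=df).fit()
            table = anova_lm(fit, typ=2)
        p_group = float(table.loc["C(group)", "PR(>F)"])
        p_stage = float(table.loc["C(stage)", "PR(>F)"])
        rows.append({"module": m, "p_group": p_group, "p_stage": p_stage,
                     "significant": bool((p_group < alpha) or (p_stage < alpha))})
    return pd.DataFrame(rows).set_index("module")


def build_network(expr: ExpressionMatrix, params: NetworkParams = NetworkParams()) -> NetworkResult:
    """Full construction: correlation -> adjacency -> TOM -> modules ->
    eigengenes -> kME."""
    cor = correlation_matrix(expr)
    adj = adjacency(cor, params.beta)
    fit_index = scale_free_fit(adj)
    t = tom(adj)
    assignment = detect_modules(t, params, expr=expr)
    if assignment.labels.max() == 0:
        me = EigengeneMatrix(values=pd.DataFrame(columns=expr.samples),
                             var_explained=pd.Series(dtype=float))
        k = pd.DataFrame(index=expr.genes)
    else:
        me = module_eigengenes(expr, assignment.labels)
        k = kme(expr, me)
    return NetworkResult(params=params, expr=expr, assignment=assignment,
                         eigengenes=me, kme=k, scale_free_index=fit_index)
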