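"""Gene-set enrichment: preranked GSEA on kME lists and classic
hypergeometric term enrichment.

The preranked mode scores whether a gene set concentrates at the top of a
list ranked by module membership (kME): a running sum adds |score|^1
(normalized) at set members and subtracts 1/(N - |S|) elsewhere; the
enrichment score ES is the maximum deviation from zero.  Significance
comes from random gene sets of equal size; NES divides ES by the mean
magnitude of same-sign null scores.  The hypergeometric mode is the
ordinary one-sided overrepresentation test of a gene list against
term -> gene annotations, BH-corrected across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import PolynetError
from .diffexpr import bh_adjust

__all__ = [
    "GeneSet",
    "gsea_preranked",
    "enrichment_score",
    "hypergeom_enrich",
]

MIN_SET_SIZE = 5


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise PolynetError(f"gene set {self.set_id!r} is empty")


def _sorted_ranking(ranked: pd.Series) -> pd.Series:
    """Descending by score; ties broken by gene id for determinism."""
    df = pd.DataFrame({"score": np.asarray(ranked, dtype=float),
                       "gene_id": [str(g) for g in ranked.index]})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True])
    return pd.Series(df["score"].to_numpy(), index=df["gene_id"].to_numpy())


def enrichment_score(ranked: pd.Series, members: set, weight: float = 1.0) -> float:
    """Signed ES of one gene set against a ranked list (running sum)."""
    srt = _sorted_ranking(ranked)
    hit = np.array([g in members for g in srt.index])
    if hit.sum() == 0 or hit.all():
        raise PolynetError("gene set must hit a strict subset of the ranking")
    w = np.abs(srt.to_numpy(float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit) / (len(srt) - hit.sum())
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_preranked(ranked: pd.Series, gene_sets, n_perm: int = 1000,
                   seed: int = 0, weight: float = 1.0) -> pd.DataFrame:
    """Preranked GSEA of one ranking (e.g., a module's kME over the network
    gene universe) against several gene sets.

    Null: ``n_perm`` random gene sets of matched size drawn from the
    universe.  Returns per set: size, ES, NES, permutation P, BH q.
    Sets overlapping the universe in fewer than 5 genes are skipped.
    """
    if isinstance(gene_sets, dict):
        gene_sets = [GeneSet(k, frozenset(v)) for k, v in gene_sets.items()]
    universe = set(ranked.index)
    rng = np.random.default_rng(seed)
    gene_arr = np.array(list(ranked.index))
    rows = []
    for gs in gene_sets:
        members = gs.genes & universe
        if len(members) < MIN_SET_SIZE:
            warnings.warn(f"gene set {gs.set_id!r} overlaps the universe in "
                          f"{len(members)} genes (< {MIN_SET_SIZE}); skipped")
            continue
        es = enrichment_score(ranked, members, weight)
        size = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            draw = set(rng.choice(gene_arr, size=size, replace=False))
            null[b] = enrichment_score(ranked, draw, weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            pval = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            pval = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + len(same_sign))
            nes = es / np.abs(same_sign).mean()
        rows.append({"set_id": gs.set_id, "size": size, "ES": es, "NES": nes,
                     "pvalue": pval})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("set_id")
        out["q"] = bh_adjust(out["pvalue"])
    return out


def hypergeom_enrich(gene_list, universe, annotations) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per annotation term.

    ``annotations`` maps term -> iterable of genes, or is a two-column
    DataFrame (gene, term).  Returns per term: counts, P, BH-adjusted P.
    """
    gene_list = set(gene_list)
    universe = set(universe)
    if not gene_list <= universe:
        raise PolynetError("gene_list must be a subset of the universe")
    if isinstance(annotations, pd.DataFrame):
        cols = list(annotations.columns[:2])
        grouped = annotations.groupby(cols[1])[cols[0]].apply(set).to_dict()
    else:
        grouped = {k: set(v) for k, v in annotations.items()}
    M = len(universe)
    n_list = len(gene_list)
    rows = []
    for term, members in sorted(grouped.items()):
        in_universe = members & universe
        if not in_universe:
            continue
        K = len(in_universe)
        k = len(in_universe & gene_list)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n_list))
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "list_size": n_list, "universe_size": M, "pvalue": p})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("term")
        out["padj"] = bh_adjust(out["pvalue"])
    return out
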