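"""Count-matrix containers, tab-separated I/O, expression filters and normalization.

The pipeline operates on homoeolog-specific read counts from an allopolyploid:
each gene pair has an A-subgenome and a D-subgenome copy, tagged with ``_A`` /
``_D`` suffixes on a shared pair stem.  The "joint" view sums the two copies
per pair and treats the pair as a single gene, mirroring a diploid-style
analysis; the "homoeologous" view keeps the copies separate.

Normalization follows the median-of-ratios convention for RNA-seq libraries,
with a log2(x/sf + 1) variance-stabilizing transform feeding the network
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "HomoeologPairing",
    "ExpressionMatrix",
    "PolynetError",
    "PairingError",
    "NormalizationError",
    "read_counts",
    "read_sample_meta",
    "read_pairing",
    "write_counts",
    "write_sample_meta",
    "write_pairing",
    "sum_pairs",
    "filter_expressed",
    "size_factors",
    "vst",
]

GROUPS = ("wild", "domesticated")
STAGES = (5, 10, 15, 20)


class PolynetError(ValueError):
    """Base error for invalid inputs to the pipeline."""


class PairingError(PolynetError):
    """A homoeolog pairing references a gene missing from the count matrix."""


class NormalizationError(PolynetError):
    """Size factors cannot be computed from the given counts."""


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers.
    ``sample_meta`` is indexed by sample id with columns ``accession``,
    ``group`` (wild / domesticated) and ``stage_dpa`` (days post-anthesis).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise PolynetError("duplicate gene identifiers in count matrix")
        if (np.asarray(self.counts.values) < 0).any():
            raise PolynetError("negative values in count matrix")
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise PolynetError(f"samples without metadata: {list(missing)[:5]}")
        # keep metadata aligned to the count columns
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.sample_meta)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.sample_meta.loc[list(samples)])


@dataclass
class HomoeologPairing:
    """Bijective A <-> D gene pair map.

    ``table`` has columns ``gene_A``, ``gene_D``, ``pair_id``; by convention
    the homoeolog ids are ``<pair_id>_A`` and ``<pair_id>_D`` but any unique
    ids are accepted.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene_A", "gene_D", "pair_id"):
            if col not in self.table.columns:
                raise PolynetError(f"pairing table missing column {col!r}")
        all_genes = pd.concat([self.table["gene_A"], self.table["gene_D"]])
        if all_genes.duplicated().any():
            raise PolynetError("a gene appears in more than one homoeolog pair")
        if self.table["pair_id"].duplicated().any():
            raise PolynetError("duplicate pair_id in pairing table")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pair_ids(self) -> pd.Index:
        return pd.Index(self.table["pair_id"])


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix on a log-like scale."""

    values: pd.DataFrame
    provenance: str = "raw-log"
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(np.asarray(self.values.values, dtype=float)).all():
            raise PolynetError("non-finite values in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# tab-separated I/O


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = read_sample_meta(meta_path)
    return CountMatrix(counts, meta)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    required = {"accession", "group", "stage_dpa"}
    if not required.issubset(meta.columns):
        raise PolynetError(f"sample metadata must have columns {sorted(required)}")
    return meta


def read_pairing(path) -> HomoeologPairing:
    return HomoeologPairing(pd.read_csv(path, sep="\t"))


def write_counts(cm: CountMatrix, counts_path, meta_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    if meta_path is not None:
        write_sample_meta(cm.sample_meta, meta_path)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def write_pairing(pairing: HomoeologPairing, path) -> None:
    pairing.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def sum_pairs(counts: CountMatrix, pairing: HomoeologPairing) -> CountMatrix:
    """Collapse homoeolog pairs to joint (A + D) counts, one row per pair_id."""
    for col in ("gene_A", "gene_D"):
        missing = pairing.table[col][~pairing.table[col].isin(counts.genes)]
        if len(missing):
            raise PairingError(f"pair member missing from counts: {missing.iloc[0]!r}")
    a = counts.counts.loc[pairing.table["gene_A"]].to_numpy()
    d = counts.counts.loc[pairing.table["gene_D"]].to_numpy()
    joint = pd.DataFrame(a + d, index=pairing.pair_ids, columns=counts.samples)
    joint.index.name = "gene"
    return CountMatrix(joint, counts.sample_meta)


def filter_expressed(counts: CountMatrix, mode: str = "joint",
                     pairing: HomoeologPairing | None = None) -> pd.Index:
    """Return genes considered expressed, preserving input order.

    ``joint`` mode keeps genes whose mean raw count over all samples is
    strictly greater than 1.  ``homoeolog`` mode keeps genes belonging to
    pairs where BOTH homoeologs have a count >= 1 in at least half of the
    libraries (the stricter pairwise reading; requires ``pairing``).
    """
    if counts.counts.shape[1] == 0 or counts.counts.shape[0] == 0:
        raise PolynetError("empty count matrix")
    if mode == "joint":
        keep = counts.counts.mean(axis=1) > 1.0
        return counts.genes[keep.to_numpy()]
    if mode == "homoeolog":
        if pairing is None:
            raise PolynetError("homoeolog mode requires a pairing table")
        n = counts.counts.shape[1]
        need = -(-n // 2)  # ceil(n/2)
        ok = (counts.counts >= 1).sum(axis=1) >= need
        ok_a = pairing.table["gene_A"].map(ok).fillna(False)
        ok_d = pairing.table["gene_D"].map(ok).fillna(False)
        pair_ok = (ok_a & ok_d).to_numpy()
        kept = set(pairing.table.loc[pair_ok, "gene_A"]) | set(pairing.table.loc[pair_ok, "gene_D"])
        return counts.genes[[g in kept for g in counts.genes]]
    raise PolynetError(f"unknown filter mode {mode!r}")


def size_factors(counts: CountMatrix, refine: bool = True) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample, the factor is the median over all-nonzero gene rows of
    count / geometric-row-mean.  Raises if no gene is nonzero in every
    sample (add a pseudocount upstream in that case).

    Median-of-ratios assumes most genes do not change across libraries;
    in developmental series where a large share of the transcriptome
    swings, the plain median leaks condition signal into the factors.
    With ``refine=True`` (default) a second pass recomputes the median
    over the stabler half of genes (lowest variance after a first-pass
    log normalization), which restores that assumption; ``refine=False``
    gives the textbook single-pass estimator.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "no gene with nonzero counts in every sample; "
            "consider adding a pseudocount before computing size factors"
        )
    sub = mat[all_nonzero]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    ratios = sub / geo
    factors = np.median(ratios, axis=0)
    if refine and ratios.shape[0] >= 20:
        resid_var = (np.log(ratios) - np.log(factors)[None, :]).var(axis=1)
        stable = resid_var <= np.median(resid_var)
        factors = np.median(ratios[stable], axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def vst(counts: CountMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """log2(count / size_factor + 1) variance-stabilized expression."""
    if factors is None:
        factors = size_factors(counts)
    f = factors.loc[counts.samples].to_numpy(dtype=float)
    if (f <= 0).any():
        raise NormalizationError("size factors must be positive")
    values = np.log2(counts.counts.to_numpy(dtype=float) / f + 1.0)
    df = pd.DataFrame(values, index=counts.genes, columns=counts.samples)
    return ExpressionMatrix(df, provenance="normalized-log", sample_meta=counts.sample_meta)
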