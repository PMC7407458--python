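"""Negative-binomial GLM differential expression.

Supports the three designs used throughout the pipeline: development +
domestication + their interaction (tested by likelihood ratio against the
main-effects model), pairwise Wald contrasts between factor levels, and the
subgenome-bias design where each homoeolog pair contributes an A and a D
observation per library.

The model is a log-link NB2 GLM with median-of-ratios size factors as
offsets and a fixed per-gene dispersion shared between nested fits.  The
dispersion is a method-of-moments (Pearson moment-matching) estimate on
normalized counts with no shrinkage, floored at 1e-8.  Fits run through
iteratively reweighted least squares; genes that fail to converge are
reported with missing P values and excluded from the Benjamini-Hochberg
denominator.

Factor coding is treatment coding with reference levels wild, the first
developmental stage, and subgenome A, so the signs of "domestication
effect" and "A vs. D" coefficients are unambiguous.  Fold changes are
reported in log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import CountMatrix, HomoeologPairing, PolynetError, size_factors

__all__ = [
    "DesignSpec",
    "DEResult",
    "NBFit",
    "DesignError",
    "build_design_matrix",
    "estimate_dispersion",
    "fit_nb_glm",
    "lrt",
    "wald_contrast",
    "classify_bias",
    "stack_homoeologs",
    "bh_adjust",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

#: reference level per factor (treatment coding)
REFERENCE_LEVELS = {"group": "wild", "stage_dpa": None, "subgenome": "A"}


class DesignError(PolynetError):
    """Invalid or rank-deficient design specification."""


@dataclass(frozen=True)
class DesignSpec:
    """Model terms over sample-metadata factors.

    ``formula`` is an ordered list of main effects (metadata column names)
    and interactions written ``"a:b"``; ``reduced`` is an optional nested
    sub-formula for likelihood-ratio testing.
    """

    formula: tuple[str, ...]
    reduced: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.reduced is not None:
            extra = set(self.reduced) - set(self.formula)
            if extra:
                raise DesignError(f"reduced terms not nested in full model: {sorted(extra)}")


@dataclass
class DEResult:
    """Per-gene test table: lfc (log2), stat, pvalue, padj."""

    table: pd.DataFrame
    test_kind: str
    contrast: str


@dataclass
class NBFit:
    """Per-gene NB GLM fits at fixed dispersion.

    ``params`` genes x coefficients (natural-log scale), ``cov`` stacked
    covariance matrices, ``llf`` log-likelihoods, ``converged`` flags,
    ``dispersion`` the shared per-gene dispersion estimates.
    """

    design_terms: tuple[str, ...]
    colnames: list[str]
    params: pd.DataFrame
    cov: np.ndarray
    llf: pd.Series
    converged: pd.Series
    dispersion: pd.Series
    meta: pd.DataFrame


def _dummy(meta: pd.DataFrame, factor: str) -> tuple[np.ndarray, list[str], list]:
    levels = list(pd.unique(meta[factor]))
    ref = REFERENCE_LEVELS.get(factor)
    if ref is None or ref not in levels:
        ref = sorted(levels, key=str)[0] if factor != "stage_dpa" else sorted(levels)[0]
    levels = [ref] + [l for l in levels if l != ref]
    cols = np.stack([(meta[factor] == l).to_numpy(float) for l in levels[1:]], axis=1) \
        if len(levels) > 1 else np.empty((len(meta), 0))
    names = [f"{factor}[{l}]" for l in levels[1:]]
    return cols, names, levels


def build_design_matrix(meta: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Treatment-coded design matrix with intercept for the given terms."""
    blocks = [np.ones((len(meta), 1))]
    names = ["Intercept"]
    for term in terms:
        if ":" in term:
            f1, f2 = term.split(":")
            c1, n1, _ = _dummy(meta, f1)
            c2, n2, _ = _dummy(meta, f2)
            for i, a in enumerate(n1):
                for j, b in enumerate(n2):
                    blocks.append((c1[:, i] * c2[:, j])[:, None])
                    names.append(f"{a}:{b}")
        else:
            if term not in meta.columns:
                raise DesignError(f"unknown design factor {term!r}")
            cols, colnames, _ = _dummy(meta, term)
            blocks.append(cols)
            names.extend(colnames)
    X = np.concatenate(blocks, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(f"rank-deficient design matrix for terms {terms}; "
                          "aliased columns among " + ", ".join(names))
    return pd.DataFrame(X, index=meta.index, columns=names)


def estimate_dispersion(counts: CountMatrix, design: tuple[str, ...],
                        factors: pd.Series | None = None,
                        method: str = "trend") -> pd.Series:
    """NB dispersion by Pearson moment matching on normalized counts.

    Per gene, solves sum((y - mu)^2 / (mu + phi mu^2)) = n - p, with mu the
    design-cell means of normalized counts, by monotone bisection; floored
    at 1e-8.  With ``method="trend"`` (default) the raw per-gene estimates
    are moderated onto a mean-dispersion trend (bin means of the raw
    estimates over mean-expression bins, interpolated in log-mean): with
    only a few replicates per design cell the raw estimates are noisy
    enough to break test calibration, and the trend removes that noise
    without any empirical-Bayes machinery.  Bin means rather than medians
    because moment matching is mean-unbiased while its sampling
    distribution is right-skewed.  ``method="per-gene"`` returns the raw
    estimates.
    """
    if factors is None:
        factors = size_factors(counts)
    y = counts.counts.to_numpy(float) / factors.to_numpy(float)[None, :]
    cells = pd.MultiIndex.from_frame(
        counts.sample_meta[[t for t in design if ":" not in t]]) if design else None
    if cells is None or len(design) == 0:
        mu = np.repeat(y.mean(axis=1, keepdims=True), y.shape[1], axis=1)
        p = 1
    else:
        codes = pd.factorize(cells)[0]
        n_cells = codes.max() + 1
        sums = np.zeros((y.shape[0], n_cells))
        cnts = np.bincount(codes, minlength=n_cells)
        for c in range(n_cells):
            sums[:, c] = y[:, codes == c].sum(axis=1)
        cell_means = sums / cnts[None, :]
        mu = cell_means[:, codes]
        p = n_cells
    n = y.shape[1]
    df = max(n - p, 1)
    mu = np.maximum(mu, 1e-8)
    resid2 = (y - mu) ** 2

    def pearson(phi):
        return (resid2 / (mu + phi[:, None] * mu ** 2)).sum(axis=1)

    lo = np.full(y.shape[0], 0.0)
    hi = np.full(y.shape[0], 10.0)
    # genes already under-dispersed at phi=0 stay at the floor
    under = pearson(lo) <= df
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_big = pearson(mid) > df  # need more dispersion
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    phi = np.where(under, DISPERSION_FLOOR, np.maximum(0.5 * (lo + hi), DISPERSION_FLOOR))
    if method == "per-gene" or len(phi) < 50:
        return pd.Series(phi, index=counts.genes, name="dispersion")
    if method != "trend":
        raise DesignError(f"unknown dispersion method {method!r}")
    log_mean = np.log(np.maximum(y.mean(axis=1), 1e-8))
    n_bins = min(20, max(len(phi) // 50, 2))
    edges = np.quantile(log_mean, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges[1:-1], log_mean), 0, n_bins - 1)
    centers, levels = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() >= 5:
            centers.append(log_mean[sel].mean())
            levels.append(phi[sel].mean())
    if len(centers) < 2:
        return pd.Series(phi, index=counts.genes, name="dispersion")
    trend = np.interp(log_mean, np.array(centers), np.array(levels))
    trend = np.maximum(trend, DISPERSION_FLOOR)
    return pd.Series(trend, index=counts.genes, name="dispersion")


def fit_nb_glm(counts: CountMatrix, design: DesignSpec,
               factors: pd.Series | None = None,
               dispersion: pd.Series | None = None,
               terms: tuple[str, ...] | None = None) -> NBFit:
    """Fit the NB2 GLM per gene at fixed dispersion with log(size factor)
    offsets.  ``terms`` overrides ``design.formula`` (used internally for
    the reduced model so the dispersion stays shared)."""
    if factors is None:
        factors = size_factors(counts)
    use_terms = design.formula if terms is None else terms
    X = build_design_matrix(counts.sample_meta, use_terms)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, design.formula, factors)
    offset = np.log(factors.loc[counts.samples].to_numpy(float))
    Xv = X.to_numpy()
    p = Xv.shape[1]
    genes = counts.genes
    params = np.full((len(genes), p), np.nan)
    cov = np.full((len(genes), p, p), np.nan)
    llf = np.full(len(genes), np.nan)
    converged = np.zeros(len(genes), dtype=bool)
    y_all = counts.counts.to_numpy(float)
    for i in range(len(genes)):
        phi = max(float(dispersion.iloc[i]), DISPERSION_FLOOR)
        fam = sm.families.NegativeBinomial(alpha=phi)
        try:
            res = sm.GLM(y_all[i], Xv, family=fam, offset=offset).fit(
                maxiter=100, tol=1e-8)
            params[i] = res.params
            cov[i] = res.cov_params()
            llf[i] = res.llf
            converged[i] = bool(getattr(res, "converged", True))
        except Exception:
            converged[i] = False
    return NBFit(
        design_terms=tuple(use_terms),
        colnames=list(X.columns),
        params=pd.DataFrame(params, index=genes, columns=X.columns),
        cov=cov,
        llf=pd.Series(llf, index=genes, name="llf"),
        converged=pd.Series(converged, index=genes, name="converged"),
        dispersion=dispersion,
        meta=counts.sample_meta,
    )


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up; NaN entries are excluded from the
    denominator and stay NaN."""
    padj = pd.Series(np.nan, index=pvalues.index, name="padj")
    mask = pvalues.notna()
    p = pvalues[mask].to_numpy(float)
    if len(p):
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        padj[mask] = out
    return padj


def lrt(full_fit: NBFit, reduced_fit: NBFit) -> DEResult:
    """Likelihood-ratio test of the full against the nested reduced model."""
    if not set(reduced_fit.design_terms) <= set(full_fit.design_terms):
        raise DesignError("reduced model is not nested in the full model")
    df = len(full_fit.colnames) - len(reduced_fit.colnames)
    if df < 0:
        raise DesignError("full model has fewer parameters than the reduced model")
    ok = full_fit.converged & reduced_fit.converged
    stat = np.maximum(2.0 * (full_fit.llf - reduced_fit.llf), 0.0)
    if df == 0:  # identical models: nothing to test
        stat = pd.Series(0.0, index=stat.index)
        pvalue = pd.Series(1.0, index=stat.index)
    else:
        pvalue = pd.Series(scipy.stats.chi2.sf(stat, df), index=stat.index)
    stat[~ok] = np.nan
    pvalue[~ok] = np.nan
    table = pd.DataFrame({
        "lfc": np.nan,
        "stat": stat,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
    })
    extra = [c for c in full_fit.colnames if c not in reduced_fit.colnames]
    return DEResult(table, test_kind="LRT", contrast="+".join(extra))


def _contrast_vector(fit: NBFit, factor: str, level1, level2) -> np.ndarray:
    c = np.zeros(len(fit.colnames))
    observed = set(pd.unique(fit.meta[factor])) if factor in fit.meta.columns else set()
    for lvl, sign in ((level1, +1.0), (level2, -1.0)):
        name = f"{factor}[{lvl}]"
        if name in fit.colnames:
            c[fit.colnames.index(name)] += sign
        elif lvl not in observed:  # reference level contributes nothing
            raise DesignError(f"unknown level {lvl!r} for factor {factor!r}")
    return c


def wald_contrast(fit: NBFit, factor: str, level1, level2) -> DEResult:
    """Wald test of ``level1`` vs. ``level2`` of a design factor.

    Positive lfc means higher expression at ``level1``; reported in log2.
    """
    c = _contrast_vector(fit, factor, level1, level2)
    coef = fit.params.to_numpy() @ c
    var = np.einsum("i,gij,j->g", c, fit.cov, c)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, coef / se, 0.0)
    pvalue = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    ok = fit.converged.to_numpy() & np.isfinite(coef) & np.isfinite(se)
    lfc = coef / LN2
    table = pd.DataFrame({
        "lfc": np.where(ok, lfc, np.nan),
        "stat": np.where(ok, stat, np.nan),
        "pvalue": np.where(ok, pvalue, np.nan),
    }, index=fit.params.index)
    table["padj"] = bh_adjust(table["pvalue"])
    return DEResult(table, test_kind="Wald", contrast=f"{factor}: {level1} vs {level2}")


# ---------------------------------------------------------------------------
# homoeolog bias


def stack_homoeologs(counts: CountMatrix, pairing: HomoeologPairing) -> CountMatrix:
    """Reshape homoeolog counts to one row per pair and doubled columns,
    adding ``subgenome`` to the sample metadata, so that A-vs-D becomes an
    ordinary factor contrast."""
    a = counts.counts.loc[pairing.table["gene_A"]].to_numpy()
    d = counts.counts.loc[pairing.table["gene_D"]].to_numpy()
    cols_a = [f"{s}:A" for s in counts.samples]
    cols_d = [f"{s}:D" for s in counts.samples]
    stacked = pd.DataFrame(np.concatenate([a, d], axis=1),
                           index=pairing.pair_ids, columns=cols_a + cols_d)
    stacked.index.name = "gene"
    meta_a = counts.sample_meta.copy()
    meta_a.index = cols_a
    meta_a["subgenome"] = "A"
    meta_d = counts.sample_meta.copy()
    meta_d.index = cols_d
    meta_d["subgenome"] = "D"
    return CountMatrix(stacked, pd.concat([meta_a, meta_d]))


def classify_bias(bias_result: DEResult, alpha: float = 0.05,
                  lfc_is_a_minus_d: bool = True) -> pd.Series:
    """Per-pair homoeolog bias call in {A, D, none} from the A-vs-D contrast."""
    tab = bias_result.table
    lfc = tab["lfc"] if lfc_is_a_minus_d else -tab["lfc"]
    sig = tab["padj"] < alpha
    call = np.where(sig & (lfc > 0), "A", np.where(sig & (lfc < 0), "D", "none"))
    return pd.Series(call, index=tab.index, name="bias_class")
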