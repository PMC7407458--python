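"""Recovery and calibration benchmarks on synthetic data.

Each function runs one self-contained study-condition experiment —
planted-module recovery, preservation calibration, co-module divergence,
differential-expression calibration, differential-correlation calibration —
and returns the measured quantities.  The published-count arithmetic
(expressed fractions, DE percentages, per-module bias chi-squares) is
recomputed from the reference tables.  Both the test suite and the
reproduction script run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix, sum_pairs, vst
from .simulate import (SimParams, make_correlated_block, simulate_dataset,
                       simulate_factorial_counts)
from .diffexpr import DesignSpec, fit_nb_glm, lrt
from .network import build_network
from .preservation import zsummary
from .homoeolog import chi_square_balance, co_module_fraction
from .diffcorr import dc_genes, dc_pairs
from .reference import STUDY_COUNTS, module_bias_counts

__all__ = [
    "recompute_bias_table_pvalues",
    "study_percentages",
    "module_recovery_ari",
    "preservation_calibration",
    "co_module_divergence",
    "de_calibration",
    "dc_calibration",
]


# ---------------------------------------------------------------------------
# published-count arithmetic


def recompute_bias_table_pvalues() -> pd.Series:
    """Chi-square balance P per module, recomputed from the published
    (A-biased, D-biased) counts and rounded to the printed two decimals."""
    table = module_bias_counts()
    out = {m: round(chi_square_balance(int(r["A_biased"]), int(r["D_biased"]))[1], 2)
           for m, r in table.iterrows()}
    return pd.Series(out, name="p_value")


def study_percentages() -> dict[str, float]:
    """Dataset-level percentages recomputed from the published counts."""
    c = STUDY_COUNTS
    return {
        "pairs_expressed_pct": round(100 * c["pairs_expressed"] / c["gene_models"], 1),
        "homoeologs_expressed_pct": round(
            100 * c["homoeologs_expressed"] / (2 * c["gene_models"]), 1),
        "development_de_pct": round(
            100 * c["development_de"] / c["homoeologs_expressed"], 1),
        "domestication_de_pct": round(
            100 * c["domestication_de"] / c["homoeologs_expressed"], 0),
        "dc_genes_pct": round(100 * c["dc_genes"] / c["homoeologs_expressed"], 1),
    }


# ---------------------------------------------------------------------------
# planted-structure recovery


def module_recovery_ari(seed: int = 1) -> float:
    """Adjusted Rand index of joint-network module detection against the
    planted labels (1,000 pairs, 4 modules of 150, noise_sd 0.1, phi 0.05)."""
    params = SimParams(n_pairs=1000, module_sizes=(150, 150, 150, 150),
                       split_fraction=0.0, rewire_fraction=0.0,
                       bias_fraction=0.2, noise_sd=0.1, dispersion=0.05,
                       seed=seed)
    truth, counts, pairing = simulate_dataset(params)
    net = build_network(vst(sum_pairs(counts, pairing)))
    labels = net.assignment.labels
    return float(adjusted_rand_score(truth.module_label_A.loc[labels.index],
                                     labels))


def preservation_calibration(seed: int = 1, n_runs: int = 20,
                             n_perm: int = 50) -> dict[str, float]:
    """Zsummary in three regimes: a planted 100-gene module (within-
    correlation ~0.9) preserved in independent test data; the same module
    with test samples shuffled per gene (signal destroyed); and random
    gene sets (|Z| < 2 expected), repeated over seeded runs."""
    rng = np.random.default_rng(seed)
    n_samples, n_bg = 24, 300
    genes = [f"g{i}" for i in range(100 + n_bg)]
    loadings = rng.uniform(0.82, 0.98, 100)
    ref = np.vstack([make_correlated_block(100, n_samples, 0.9, rng,
                                           loadings=loadings),
                     rng.normal(size=(n_bg, n_samples))])
    test = np.vstack([make_correlated_block(100, n_samples, 0.9, rng,
                                            loadings=loadings),
                      rng.normal(size=(n_bg, n_samples))])
    ref_e = ExpressionMatrix(pd.DataFrame(ref, index=genes,
                                          columns=[f"s{j}" for j in range(n_samples)]))
    test_e = ExpressionMatrix(pd.DataFrame(test, index=genes,
                                           columns=[f"t{j}" for j in range(n_samples)]))
    labels = pd.Series([1] * 100 + [0] * n_bg, index=genes)
    z_preserved = zsummary(labels, ref_e, test_e, n_perm=n_perm,
                           seed=seed).table.loc[1, "Zsummary"]

    destroyed = test.copy()
    for row in destroyed:
        rng.shuffle(row)
    destroyed_e = ExpressionMatrix(pd.DataFrame(destroyed, index=genes,
                                                columns=test_e.samples))
    z_destroyed = zsummary(labels, ref_e, destroyed_e, n_perm=n_perm,
                           seed=seed).table.loc[1, "Zsummary"]

    ok = 0
    for r in range(n_runs):
        run_rng = np.random.default_rng([seed, 101 + r])
        pick = run_rng.choice(len(genes), 50, replace=False)
        rand_labels = pd.Series(0, index=pd.Index(genes))
        rand_labels.iloc[pick] = 1
        z = zsummary(rand_labels, ref_e, test_e, n_perm=n_perm,
                     seed=seed + r).table.loc[1, "Zsummary"]
        ok += abs(z) < 2
    return {"z_preserved": float(z_preserved),
            "z_destroyed": float(z_destroyed),
            "random_within_2_fraction": ok / n_runs}


def co_module_divergence(seed: int = 1) -> dict[str, float]:
    """Co-module fraction of homoeolog pairs in the homoeologous network
    under planted divergence 0.8 (expect ~0.2) and 0 (expect ~1)."""
    out = {}
    for split, key in ((0.8, "fraction_split_080"), (0.0, "fraction_split_000")):
        params = SimParams(split_fraction=split, rewire_fraction=0.0,
                           noise_sd=0.1, seed=seed)
        truth, counts, pairing = simulate_dataset(params)
        net = build_network(vst(counts))
        labels = net.assignment.labels
        out[key] = co_module_fraction(labels, labels, pairing).fraction
    return out


# ---------------------------------------------------------------------------
# test calibration


_FACTORIAL_DESIGN = DesignSpec(formula=("group", "stage_dpa", "group:stage_dpa"),
                               reduced=("group", "stage_dpa"))


def _interaction_lrt(counts):
    full = fit_nb_glm(counts, _FACTORIAL_DESIGN)
    reduced = fit_nb_glm(counts, _FACTORIAL_DESIGN, dispersion=full.dispersion,
                         terms=_FACTORIAL_DESIGN.reduced)
    return lrt(full, reduced)


def de_calibration(seed: int = 1, n_null: int = 2000,
                   n_power: int = 2000) -> dict[str, float]:
    """Interaction LRT calibration: raw type-I error on a null factorial
    simulation, and BH power for 500 genes with a planted interaction of
    log2 fold change 2 at 3 replicates per design cell, phi 0.05."""
    null_counts = simulate_factorial_counts(n_null, interaction_lfc=0.0,
                                            phi=0.05, seed=seed)
    null_p = _interaction_lrt(null_counts).table["pvalue"].dropna()
    type1 = float((null_p < 0.05).mean())

    frac = 500 / n_power
    power_counts = simulate_factorial_counts(n_power, interaction_lfc=2.0,
                                             interaction_fraction=frac,
                                             phi=0.05, seed=seed + 1)
    res = _interaction_lrt(power_counts).table
    planted = res.index[:500]
    power = float((res.loc[planted, "padj"] < 0.05).mean())
    return {"lrt_type1_error": type1, "lrt_power": power}


def dc_calibration(seed: int = 1) -> dict[str, float]:
    """Differential-correlation calibration on homoeolog data (wild vs.
    domesticated, 12 + 12 libraries): fraction of BH-flagged DC genes with
    no planted rewiring, and recovery of 50 sign-flipped module genes."""
    def run(rewire_fraction, run_seed):
        params = SimParams(n_pairs=500, module_sizes=(50, 50, 50),
                           split_fraction=0.0, rewire_fraction=rewire_fraction,
                           bias_fraction=0.2, noise_sd=0.2, dispersion=0.05,
                           seed=run_seed)
        truth, counts, _ = simulate_dataset(params)
        expr = vst(counts)
        meta = expr.sample_meta
        wild_cols = list(meta.index[meta["group"] == "wild"])
        dom_cols = list(meta.index[meta["group"] == "domesticated"])
        ew = ExpressionMatrix(expr.values[wild_cols], sample_meta=meta.loc[wild_cols])
        ed = ExpressionMatrix(expr.values[dom_cols], sample_meta=meta.loc[dom_cols])
        pairs = dc_pairs(ew, ed, method="bh")
        return truth, dc_genes(pairs)

    _, null_genes = run(0.0, seed)
    null_fraction = float(null_genes.table["dc_flag"].mean())
    truth, rewired_genes = run(50 / 300, seed)  # 50 of 300 module genes flipped
    rew = truth.rewired_genes
    recovery = float(rewired_genes.table["dc_flag"].loc[rew].mean())
    return {"null_dc_gene_fraction": null_fraction,
            "rewired_recovery": recovery, "n_rewired": int(len(rew))}
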