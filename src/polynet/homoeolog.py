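"""Joint vs. homoeologous network comparison.

Two questions about duplicated genes in an allopolyploid network: do the A
and D copies of a pair land in the same coexpression module when analyzed
separately (co-module co-occurrence), and do modules of the joint network
carry more A- or D-biased pairs than expected under balance (a per-module
chi-square goodness-of-fit test on the biased-pair counts)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import HomoeologPairing, PolynetError

__all__ = [
    "CoModuleResult",
    "co_module_fraction",
    "chi_square_balance",
    "module_bias_table",
]


@dataclass
class CoModuleResult:
    """Pair co-assignment summary.

    ``fraction`` = co-assigned pairs / denominator.  ``n_comodule`` counts
    pairs whose two copies share a nonzero module label; pairs with either
    copy unassigned are reported separately in ``n_unassigned`` and only
    count toward the denominator when it is "all".
    """

    fraction: float
    n_comodule: int
    n_assigned: int
    n_unassigned: int
    n_pairs: int
    denominator: str


def co_module_fraction(labels_A: pd.Series, labels_D: pd.Series,
                       pairing: HomoeologPairing,
                       denominator: str = "assigned") -> CoModuleResult:
    """Fraction of homoeolog pairs whose two copies share a module.

    ``labels_A`` / ``labels_D`` are gene -> module labels from the same
    homoeologous network run (they may be the same Series covering all
    genes).  ``denominator`` is one of ``assigned`` (pairs with both copies
    in a nonzero module), ``expressed`` (pairs with both copies labelled at
    all) or ``all`` (every pair in the pairing table).
    """
    if len(pairing) == 0:
        raise PolynetError("empty pairing table")
    la = pairing.table["gene_A"].map(labels_A)
    ld = pairing.table["gene_D"].map(labels_D)
    present = la.notna() & ld.notna()
    both_assigned = present & (la > 0) & (ld > 0)
    matched = both_assigned & (la == ld)
    n_assigned = int(both_assigned.sum())
    n_matched = int(matched.sum())
    n_unassigned = int((present & ~both_assigned).sum())
    denominators = {
        "assigned": n_assigned,
        "expressed": int(present.sum()),
        "all": len(pairing),
    }
    if denominator not in denominators:
        raise PolynetError(f"unknown denominator {denominator!r}")
    denom = denominators[denominator]
    fraction = n_matched / denom if denom else np.nan
    return CoModuleResult(fraction=fraction, n_comodule=n_matched,
                          n_assigned=n_assigned, n_unassigned=n_unassigned,
                          n_pairs=len(pairing), denominator=denominator)


def chi_square_balance(n_A: int, n_D: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of (n_A, n_D) against a 50:50 split.

    df = 1, no continuity correction.  Returns (statistic, two-sided P);
    (0, 0) counts give (nan, nan).
    """
    if n_A < 0 or n_D < 0:
        raise PolynetError("counts must be non-negative")
    total = n_A + n_D
    if total == 0:
        return (np.nan, np.nan)
    e = total / 2.0
    stat = (n_A - e) ** 2 / e + (n_D - e) ** 2 / e
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return float(stat), p


def module_bias_table(joint_labels: pd.Series, bias_classes: pd.Series,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-module homoeolog bias table.

    For each joint-network module (including 0, the unassigned bin):
    counts of A- and D-biased member pairs, the balance chi-square P, and
    the module-level call (A-bias / D-bias when P < alpha, else balanced).
    A final ``Sum`` row aggregates all biased pairs.
    """
    shared = joint_labels.index.intersection(bias_classes.index)
    lab = joint_labels.loc[shared]
    cls = bias_classes.loc[shared]
    rows = []
    for m in sorted(lab.unique()):
        members = cls[lab == m]
        n_a = int((members == "A").sum())
        n_d = int((members == "D").sum())
        rows.append(_bias_row(m, n_a, n_d, alpha))
    total_a = int((cls == "A").sum())
    total_d = int((cls == "D").sum())
    rows.append(_bias_row("Sum", total_a, total_d, alpha))
    out = pd.DataFrame(rows).set_index("module")
    return out


def _bias_row(module, n_a: int, n_d: int, alpha: float) -> dict:
    stat, p = chi_square_balance(n_a, n_d)
    if np.isnan(p):
        call = "NA"
    elif p < alpha:
        call = "A-bias" if n_a > n_d else "D-bias" if n_d > n_a else "balanced"
    else:
        call = "balanced"
    return {"module": module, "total": n_a + n_d, "A_biased": n_a,
            "D_biased": n_d, "chi2": stat, "p_value": p, "call": call}
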