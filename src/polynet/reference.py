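"""Published summary counts from the wild-vs-domesticated cotton fiber
coexpression study this pipeline models.

These are printed dataset-level numbers (gene-model totals, expressed
counts, differential-expression counts, and the per-module homoeolog bias
contingency table of the joint network).  They serve as fixed inputs for
arithmetic and contingency-table re-computation; they are not outputs of
this package's simulations.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["STUDY_COUNTS", "MODULE_BIAS_COUNTS", "module_bias_counts"]

#: headline counts of the original study
STUDY_COUNTS = {
    # reference gene models in the diploid D-genome assembly
    "gene_models": 37_505,
    # homoeolog pairs with joint expression during fiber development
    "pairs_expressed": 29_706,
    # individually expressed homoeologs (A + D)
    "homoeologs_expressed": 50_996,
    "homoeologs_expressed_A": 25_474,
    "homoeologs_expressed_D": 25_522,
    # homoeologs with a significant development effect (printed table value)
    "development_de": 29_671,
    # homoeologs with a significant domestication effect
    "domestication_de": 10_218,
    # homoeologs with a significant interaction effect
    "interaction_de": 85,
    # genes flagged as differentially coexpressed (DC) wild vs. domesticated
    "dc_genes": 16_503,
    # homoeolog pairs with significant expression bias, and the split
    "biased_pairs": 16_273,
    "biased_pairs_A": 7_752,
    "biased_pairs_D": 8_521,
    # pairs co-assigned to one module in the homoeologous network
    "comodule_pairs": 7_561,
    # module counts: joint / homoeologous / wild / domesticated networks
    "modules_joint": 26,
    "modules_homoeologous": 52,
    "modules_wild": 107,
    "modules_domesticated": 47,
}

#: per-module (A-biased, D-biased) pair counts of the joint network,
#: with the two-decimal chi-square P value as printed
MODULE_BIAS_COUNTS = [
    # (module, total, A_biased, D_biased, printed_p, printed_call)
    (0, 615, 280, 335, 0.03, "D-bias"),
    (1, 3747, 1800, 1947, 0.02, "D-bias"),
    (2, 4591, 2180, 2411, 0.00, "D-bias"),
    (3, 1072, 498, 574, 0.02, "D-bias"),
    (4, 754, 360, 394, 0.22, ""),
    (5, 665, 339, 326, 0.61, ""),
    (6, 567, 251, 316, 0.01, "D-bias"),
    (7, 497, 220, 277, 0.01, "D-bias"),
    (8, 497, 242, 255, 0.56, ""),
    (9, 481, 229, 252, 0.29, ""),
    (10, 302, 118, 184, 0.00, "D-bias"),
    (11, 252, 117, 135, 0.26, ""),
    (12, 288, 128, 160, 0.06, ""),
    (13, 251, 124, 127, 0.85, ""),
    (14, 261, 118, 143, 0.12, ""),
    (15, 240, 216, 24, 0.00, "A-bias"),
    (16, 186, 80, 106, 0.06, ""),
    (17, 122, 61, 61, 1.00, ""),
    (18, 240, 101, 139, 0.01, "D-bias"),
    (19, 132, 61, 71, 0.38, ""),
    (20, 185, 87, 98, 0.42, ""),
    (21, 33, 13, 20, 0.22, ""),
    (22, 34, 19, 15, 0.49, ""),
    (23, 77, 39, 38, 0.91, ""),
    (24, 71, 27, 44, 0.04, "D-bias"),
    (25, 65, 24, 41, 0.03, "D-bias"),
    (26, 48, 20, 28, 0.25, ""),
]


def module_bias_counts() -> pd.DataFrame:
    """The published per-module bias contingency table as a DataFrame."""
    df = pd.DataFrame(MODULE_BIAS_COUNTS, columns=[
        "module", "total", "A_biased", "D_biased", "printed_p", "printed_call"])
    return df.set_index("module")
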