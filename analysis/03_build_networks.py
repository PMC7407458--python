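#!/usr/bin/env python
"""Build the four coexpression networks: joint (summed pairs),
homoeologous (individual copies), wild-only and domesticated-only.

Normalizes with median-of-ratios + log2, constructs unsigned beta=12
networks, detects modules, and tests module eigengenes against
domestication group and developmental stage (ANOVA).  Writes module
assignments, eigengenes, kME and the ANOVA table under results/networks/.
"""

from pathlib import Path

import pandas as pd

from polynet.io import (ExpressionMatrix, filter_expressed, read_counts,
                        read_pairing, sum_pairs, vst)
from polynet.network import NetworkParams, build_network, me_condition_anova

DATA = Path("results/data")
OUT = Path("results/networks")


def main() -> None:
    counts = read_counts(DATA / "counts.tsv", DATA / "sample_meta.tsv")
    pairing = read_pairing(DATA / "pairing.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    params = NetworkParams()

    joint = sum_pairs(counts, pairing)
    joint = joint.subset_genes(filter_expressed(joint, "joint"))
    homoeo = counts.subset_genes(filter_expressed(counts, "homoeolog",
                                                  pairing=pairing))
    joint_expr = vst(joint)
    homoeo_expr = vst(homoeo)

    networks = {"joint": build_network(joint_expr, params),
                "homoeologous": build_network(homoeo_expr, params)}
    meta = homoeo_expr.sample_meta
    for grp in ("wild", "domesticated"):
        cols = list(meta.index[meta["group"] == grp])
        sub = ExpressionMatrix(homoeo_expr.values[cols], sample_meta=meta.loc[cols])
        networks[grp] = build_network(sub, params)

    rows = []
    for name, net in networks.items():
        net.assignment.labels.to_frame().to_csv(OUT / f"modules_{name}.tsv",
                                                sep="\t", index_label="gene")
        net.eigengenes.values.to_csv(OUT / f"eigengenes_{name}.tsv", sep="\t")
        net.kme.to_csv(OUT / f"kme_{name}.tsv", sep="\t", index_label="gene")
        sizes = net.assignment.module_sizes
        rows.append({"network": name,
                     "n_genes": len(net.assignment.labels),
                     "n_modules": len(net.eigengenes.modules),
                     "unassigned": int(sizes.get(0, 0)),
                     "scale_free_fit": round(net.scale_free_index, 3)})
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    anova = me_condition_anova(networks["homoeologous"].eigengenes, meta)
    anova.to_csv(OUT / "me_condition_anova.tsv", sep="\t")
    n_sig = int(anova["significant"].sum())
    print(f"{n_sig} of {len(anova)} homoeologous-network module eigengenes "
          "are associated with stage and/or domestication (ANOVA P < 0.05)")


if __name__ == "__main__":
    main()
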