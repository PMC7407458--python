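#!/usr/bin/env python
"""Gene-set enrichment of DE categories on module membership.

For each homoeologous-network module, ranks all genes by kME and runs
preranked GSEA of the domestication-DE and interaction-DE gene sets,
asking which modules concentrate differential expression at their core.
Writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from polynet.enrichment import gsea_preranked

NETS = Path("results/networks")
DE = Path("results/de")
OUT = Path("results/enrichment")
ALPHA = 0.05
N_PERM = 500
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    kme = pd.read_csv(NETS / "kme_homoeologous.tsv", sep="\t", index_col=0)
    kme.columns = [int(c) for c in kme.columns]
    sets = {}
    for name, path in (("domestication_DE", DE / "domestication.tsv"),
                       ("interaction_DE", DE / "interaction_lrt.tsv")):
        tab = pd.read_csv(path, sep="\t", index_col=0)
        members = set(tab.index[tab["padj"] < ALPHA])
        if len(members) >= 5:
            sets[name] = members
    if not sets:
        print("no DE gene set large enough to test")
        return

    tables = []
    for m in kme.columns:
        res = gsea_preranked(kme[m], sets, n_perm=N_PERM, seed=SEED)
        if len(res):
            res = res.reset_index()
            res.insert(0, "module", m)
            tables.append(res)
    enr = pd.concat(tables, ignore_index=True)
    enr.to_csv(OUT / "gsea_module_enrichment.tsv", sep="\t", index=False)
    sig = enr[enr["q"] < ALPHA]
    print(f"{len(sig)} of {len(enr)} (module, DE-set) tests enriched at "
          f"q < {ALPHA}:")
    if len(sig):
        print(sig[["module", "set_id", "ES", "NES", "pvalue", "q"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
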