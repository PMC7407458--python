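# polynet

Duplicated coexpression-network analysis for allopolyploid transcriptomes.

Allopolyploid species such as Upland cotton (*Gossypium hirsutum*) carry two
co-resident subgenomes (A and D), so almost every gene exists as a duplicated
homoeolog pair. When expression is profiled across a developmental series in
wild and domesticated accessions, three questions arise that ordinary
single-genome pipelines cannot answer:

1. **Do the duplicated copies stay co-regulated?** Build one network from the
   *summed* expression of each pair (the "joint" network, treating the pair
   like a diploid gene) and one from the individual copies (the
   "homoeologous" network), then ask whether joint modules are preserved in
   each subgenome's data and how often the two copies of a pair land in the
   same module.
2. **Which subgenome is expressed more?** Per-pair A-vs-D contrasts in a
   negative-binomial GLM give homoeolog-bias calls, cross-tabulated against
   modules with chi-square balance tests.
3. **What did domestication rewire?** Separate wild and domesticated
   networks are compared by permutation module-preservation statistics, and
   gene pairs whose correlation changed are detected directly by Fisher's
   z-test with a binomial model for "DC genes".

The package implements the full pipeline — filtering and normalization,
NB-GLM differential expression, WGCNA-style weighted networks, module
preservation, bias tables, differential correlation, and kME-ranked gene-set
enrichment — plus a synthetic-data generator that emulates the study design
(24 libraries = 2 domestication groups × 4 stages × 3 accessions) with
planted modules, bias, inter-module divergence of duplicates, and
domestication rewiring, so every stage is testable against known ground
truth without any sequencing data.

## Core statistics

* **Networks.** Pearson correlation `r_ij` between log-normalized profiles;
  unsigned soft-threshold adjacency `a_ij = |r_ij|^β` (β = 12); topological
  overlap `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `ℓ_ij = Σ_u a_iu a_uj`; average-linkage clustering of `1 − TOM` with a
  static cut, minimum module size, eigengene-based merging and kME-based
  cleanup/rescue. Module eigengene (ME) = first principal component of the
  module's standardized expression; `kME_i = cor(x_i, ME)`.
* **Differential expression.** NB2 GLM with log link, median-of-ratios size
  factor offsets and trend-moderated method-of-moments dispersion;
  interaction tested by likelihood ratio of
  `~ domestication + development + domestication:development` against the
  main-effects model (χ² df = 3); pairwise Wald contrasts; homoeolog bias by
  an A-vs-D subgenome contrast, BH-corrected.
* **Preservation.** Four statistics per module (mean intramodule
  correlation and adjacency; correlation of intramodular connectivity and
  of correlation patterns between datasets), standardized against a
  permuted-label null: `Zsummary = (Zdensity + Zconnectivity) / 2` with
  the conventional reading > 10 strong, 2–10 moderate, < 2 none; medianRank
  compares modules to each other.
* **Differential correlation.** `z = (atanh r_wild − atanh r_dom) /
  sqrt(1/(n_w−3) + 1/(n_d−3))`; pair significance by local FDR (default) or
  BH; per-gene DC calls from the binomial upper tail `Pr[X ≥ k]`,
  `X ~ Bin(n, p0)` at the global significant-pair rate `p0`, BH-corrected.
* **Enrichment.** Preranked GSEA on kME-ranked lists (running sum weighted
  by |kME|, random gene-set null, NES) and classic hypergeometric
  overrepresentation.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `analysis/01_simulate_dataset.py` generates the default design and
prints:

```
simulated 2000 homoeologs x 24 libraries (seed 1)
  planted modules: (200, 200, 200, 200); split pairs: 800; rewired genes: 527; biased pairs: 550
```

i.e., 1,000 pairs with four planted modules, 80% of pairs whose two copies
belong to different modules, ~30% of module genes sign-flipped in the
domesticated group, and 55% of pairs with a ±0.5 log2 A/D shift. Running
`analysis/05_homoeolog_bias.py` and `analysis/06_differential_correlation.py`
afterwards prints:

```
module bias table: 3 of 10 joint modules show significant homoeolog bias; overall call: D-bias
co-module pairs: 104 of 889 assigned pairs (11.7%); planted divergence 0.8 caps this at ~20%, and rewiring depresses it further
26414 of 319600 gene pairs are differentially correlated; 206 of 800 genes flagged as DC genes (global pair rate p0 = 0.0826)
planted rewired genes among tested: 201; fraction recovered as DC genes: 100.0%
```

The module-level bias calls, the low co-module fraction of duplicated
copies, and the complete recovery of the planted rewired genes as DC genes
are the three signatures the pipeline is built to measure. The same stages
are available as a CLI (`polynet simulate/prepare/de/network/preserve/
bias-table/diffcorr/enrich/run`); `polynet run --config cfg.yaml` executes
everything end to end and writes a run manifest.

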