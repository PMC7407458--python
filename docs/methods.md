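# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the pipeline. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis pipeline

### Filtering and normalization

Genes are "expressed" in the joint (pair-summed) view when their mean raw
count over all libraries is strictly greater than 1; in the homoeolog view
a pair is kept when **both** copies have ≥ 1 read in at least ⌈n/2⌉
libraries (the stricter pairwise reading of an ambiguous rule; the
per-copy alternative would keep half-expressed pairs whose bias contrast
is then ill-defined).

Library size factors are median-of-ratios: for each library, the median
over all-nonzero gene rows of count / geometric-row-mean. Median-of-ratios
assumes most genes are stable across libraries; in a developmental series
where a large fraction of the transcriptome swings several-fold, the plain
median leaks condition signal into the factors, and that error — being
shared by every gene in a library — becomes a spurious common expression
factor downstream. The default therefore adds one refinement pass: genes
are ranked by the variance of their log ratios after the first-pass
normalization, and the median is recomputed over the stabler half
(`refine=False` gives the textbook single-pass estimator). Expression for
network construction is `log2(count/sf + 1)`. This replaces a regularized
log transform: the variance-stabilizing intent is preserved and nothing
downstream depends on the exact transform, only on correlations of
log-scale profiles.

### Differential expression

Per gene, an NB2 GLM (variance μ + φμ²) with log link and log size-factor
offsets, fitted by IRLS at a fixed per-gene dispersion. Dispersion is
estimated by Pearson moment matching on normalized counts — solve
Σ (y − μ̂)²/(μ̂ + φμ̂²) = n − p with μ̂ the design-cell means — and then
moderated onto a mean-dispersion trend (bin means of the raw estimates
over 20 mean-expression quantile bins, interpolated in log mean). The
moderation matters: with 3 replicates per cell the raw estimate has ~35%
sampling CV, and plugging such noisy values into a χ² likelihood-ratio
test inflates the type-I error to ~0.09–0.11 through the convex tail;
the trend restores calibration (~0.06 measured on a 2,000-gene null) with
plain cross-gene pooling, no empirical-Bayes posterior. Bin means rather
than medians because the moment estimator is mean-unbiased but
right-skewed. The estimate is shared between full and reduced fits.

The interaction is tested by LRT (χ², df = number of extra coefficients);
pairwise contrasts by Wald tests on treatment-coded coefficients
(references: wild, first stage, subgenome A), reported as log2 fold
changes; BH correction throughout, with non-convergent genes reported as
NA and excluded from the BH denominator. Homoeolog bias reshapes the pair
matrix to one row per pair and 2n columns with a `subgenome` factor, fits
`~ subgenome + domestication + development`, and calls a pair A- or
D-biased when the BH-adjusted subgenome contrast P < 0.05, with the sign
of the A−D fold change giving the direction.

### Networks

Unsigned WGCNA-style construction: Pearson correlation → `|r|^β` with
β = 12 (a `pick_beta` helper exposes the smallest power reaching a
scale-free fit index of 0.8, the criterion used to justify the default) →
topological overlap → average-linkage clustering of 1 − TOM
(`scipy.cluster.hierarchy`; tie-breaks follow deterministic input order).
The dynamic tree cut is replaced by: static cut at 0.99 × the maximum
merge height, minimum module size 30, iterative merging of modules whose
eigengene dissimilarity is below 0.15, removal of assigned genes whose
own-module |kME| is below 0.3 (mirroring the default membership cleanup of
the standard automatic construction), and rescue of unassigned genes with
kME > 0.7. Labels are renumbered by descending size, 0 = unassigned.
Module eigengenes are the first right singular vector of the
gene-standardized module submatrix, oriented for positive mean member
correlation; kME is the gene × eigengene correlation matrix. Eigengene–
condition association uses a two-way ANOVA (`ME ~ group + stage`,
categorical, type-II F tests).

### Module preservation

Four statistics per module, computable from expression alone: meanCor and
meanAdj (density in the test data), cor_kIM and cor_cor (connectivity
pattern agreement between reference and test). The published framework
uses roughly seven; the four here are the ones that drive the density and
connectivity medians without requiring the reference network's adjacency
beyond expression. The null permutes module labels among genes (sizes
preserved, default 100 permutations); Zdensity/Zconnectivity are medians
of their two Zs and Zsummary their mean. Boundaries: Zsummary = 2 and
= 10 are classified "moderate" (closed interval). Module 0 is never
tested. A caveat observed on synthetic data: when a permuted null set
mixes genes from a real module with background, its cross-dataset
connectivity correlation can exceed the within-module value, so
individual connectivity Zs can go negative for genuinely preserved
modules; the composite Zsummary remains well-behaved in the planted
regimes the acceptance suite checks.

### Differential correlation

All unordered gene pairs; Fisher z on the per-group correlations with n =
libraries per group (12 in the emulated design — the number of
observations entering each correlation, not the number of accessions).
Default pair-level significance is a local FDR under a two-group model
with theoretical N(0,1) null: the marginal density is a
Gaussian-smoothed histogram, π₀ = min(1, f(0)/φ(0)), and the lfdr is made
monotone non-increasing in |z| by isotonic regression; BH on the
two-sided P values is the documented alternative (and the default in the
calibration benchmarks, since lfdr estimation is implementation-
sensitive). DC genes: k significant pairs among n tested partners,
binomial upper tail at the global rate p0, BH across genes.

### Enrichment

Preranked GSEA with weight exponent 1 on |kME|, null from random gene
sets of matched size (default 1,000 permutations; the preranked setting
rules out sample permutation), NES = ES / mean |same-sign null ES|, and a
BH q over tested sets. Hypergeometric overrepresentation treats
annotations as flat term → gene sets; no ontology-graph decorrelation and
no semantic summarization of terms.

## The synthetic-data generator

The generator emulates the study design — 24 libraries = 2 domestication
groups × 4 stages (5/10/15/20 dpa) × 3 accessions, A and D copies per
pair — with these components on the log2 scale:

`log2 μ_gs = baseline_g + s_gs · loading_g · activity_g(s) + bias_g +
log2 lib_s + ε_gs`, counts ~ NB(μ, φ) via gamma–Poisson (φ = 0 gives
deterministic rounded means).

* **Module programs.** Each planted module has a latent stage program;
  member genes follow it through a loading drawn uniform 0.6–1.0 (this
  gradient is what gives modules hubs and peripheries). Programs are a
  minimal-coherence frame in the zero-mean stage space: exactly orthogonal
  for up to 3 modules, the regular simplex frame (pairwise correlation
  −1/3) for 4 — so module identity is a property of the design, not an
  accident of a random draw. The domesticated program is one common
  rotation (a timing shift) of the wild program plus a module-level
  N(0, 1) offset. The rotation gives genuine domestication × development
  structure; because a common rotation preserves the Gram matrix of the
  programs, every gene pair has *identical population correlation in both
  groups*, making planted rewiring the only source of differential
  correlation — the property the DC calibration criteria require. The
  offset creates domestication DE without touching within-group
  correlations. Amplitude: per-condition RMS 2.0 log2 (~4-fold typical
  swings).
* **Background pairs** follow a private per-library profile (amplitude
  0.5 log2) shared by the two copies of a pair: per-library rather than
  per-condition so background genes have no reproducible coexpression,
  shared within pair so that the bias term remains the only systematic
  A/D difference, and small enough that the bulk of genes anchors
  median-of-ratios normalization as in real libraries.
* **Bias** is a symmetric ± bias_lfc/2 shift on the A vs. D copy of a
  chosen fraction of pairs (direction 50:50), leaving the joint sum
  approximately bias-invariant.
* **Divergence (split)** reassigns the D copy of ⌊split_fraction ·
  n_pairs⌋ pairs to a different planted module.
* **Rewiring** sign-flips the loading of a fraction of module-assigned
  genes in the domesticated group only; the domesticated-truth label is
  recorded as m + n_modules to mark the anti-correlated variant.
* **Determinism.** One seeded generator for the truth (draw order: module
  programs, private profiles, baselines/loadings, split, bias, rewiring)
  and one derived generator for counts; identical parameters give
  bit-identical output.

Defaults mirror the emulated study regime: 1,000 pairs, 4 × 200 module
pairs, bias fraction 0.55 (roughly the biased share among testable pairs
in the study), bias lfc 1.0, split 0.8 (the study found ~1/5 of pairs
co-assigned), rewire 0.3 (roughly a third of genes differentially
correlated), φ = 0.05, noise 0.2 log2, library factors 0.7–1.4.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mapping and read-assignment noise between
homoeologs, dispersion that varies across genes, unbalanced or missing
libraries, correlated accession (genotype) effects, overlapping or nested
modules, and any ontology structure in annotations. Because rewiring is a
pure sign flip, it is invisible to the *unsigned* network and to the
preservation statistics (the analysis scripts point this out); it is the
differential-correlation stage that detects it, which matches the role
the two analyses play.

## Benchmarks and problem sizes

The acceptance suite runs at desk scale, chosen so the full suite
finishes in a couple of minutes: module recovery on 1,000 pairs (4 × 150
planted, noise 0.1, φ = 0.05, ARI vs. truth); preservation on a planted
100-gene module (within-correlation ~0.9 with loading heterogeneity
±0.08 — a flat equicorrelated block has no connectivity pattern to
preserve and cannot reach the strong-preservation regime) over 300
background genes with 50 permutations; co-module divergence at the
default design; DE calibration on 2,000-gene factorial nulls and 500
planted-interaction genes among 2,000 (a planted effect shared by *all*
genes would be absorbed by normalization); DC calibration on 500 pairs
with 50 of 300 module genes flipped. Published-count arithmetic
(percentages and chi-square P values, no continuity correction — the
uncorrected statistic reproduces the printed two-decimal P column) is
exact and instantaneous.

## Known limitations

* The static-cut module detection approximates, not replicates, dynamic
  tree cutting; absolute module counts on real data will differ from the
  reference implementation even where planted-structure recovery is good.
* Per-gene dispersion is trend-only; genuinely outlying genes are tested
  at the trend dispersion and can be mis-calibrated individually.
* The local FDR estimator is histogram-based and intended for ≥ a few
  thousand tests; below 100 tests it falls back to BH.
* Preservation Z values are unbounded when the permutation null
  degenerates (e.g., very strong small modules at β = 12); comparisons
  across module sizes are safest through medianRank.
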