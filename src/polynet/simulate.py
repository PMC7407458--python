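"""Synthetic homoeolog-pair count data with planted network structure.

The generator emulates a wild-vs-domesticated allopolyploid fiber study
design: 24 RNA-seq libraries = 2 domestication groups x 4 developmental
stages (5/10/15/20 dpa) x 3 accessions, with an A- and a D-subgenome copy
per gene pair.  It plants, with full ground truth:

* coexpression modules — each module has a latent log2 activity profile over
  the 8 group x stage conditions; member genes follow it through a positive
  loading (uniform 0.6–1.0), so the module eigengene structure downstream
  is real rather than assumed;
* homoeolog expression bias — a fraction of pairs get a symmetric
  +/- bias_lfc/2 shift on the A vs. D copy, leaving the joint (summed)
  signal approximately bias-invariant;
* co-module divergence — a fraction of pairs have their D copy reassigned
  to a different planted module, mimicking inter-module divergence of
  duplicated genes;
* domestication rewiring — a fraction of module genes have their loading
  sign-flipped in the domesticated group only, creating maximal, countable
  wild-vs-domesticated correlation changes (the differential-correlation
  ground truth).

Counts are negative-binomial around the exponentiated latent means with a
gamma-Poisson draw; dispersion 0 degenerates to deterministic rounded means.
A single seed controls everything; identical parameters give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, HomoeologPairing, PolynetError

__all__ = [
    "SimParams",
    "GroundTruth",
    "generate_truth",
    "simulate_counts",
    "simulate_dataset",
    "make_sample_meta",
    "make_correlated_block",
    "simulate_factorial_counts",
]

#: log2-scale amplitude of module latent profiles (typical developmental
#: swings of ~4-fold either way)
LATENT_AMPLITUDE = 2.0
#: log2-scale amplitude of background genes' private per-library variation;
#: kept well below the module amplitude so that the bulk of genes is stable
#: enough to anchor median-of-ratios normalization, as in real libraries
BACKGROUND_AMPLITUDE = 0.5
#: log2-scale baseline expression range (counts roughly 32–512)
BASELINE_RANGE = (5.0, 9.0)
#: loading range tying a member gene to its module latent profile
LOADING_RANGE = (0.6, 1.0)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated study regime: 24 libraries, strong
    inter-module divergence of duplicated copies (split_fraction 0.8 gives
    roughly one fifth of pairs co-assigned), roughly half the pairs biased,
    and about a third of module genes rewired by domestication.
    """

    n_pairs: int = 1000
    module_sizes: tuple[int, ...] = (200, 200, 200, 200)
    n_accessions: int = 3
    timepoints: tuple[int, ...] = (5, 10, 15, 20)
    bias_fraction: float = 0.55
    bias_lfc: float = 1.0
    split_fraction: float = 0.8
    rewire_fraction: float = 0.3
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    noise_sd: float = 0.2
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def groups(self) -> tuple[str, str]:
        return ("wild", "domesticated")

    @property
    def conditions(self) -> list[str]:
        return [f"{g}_{t}" for g in self.groups for t in self.timepoints]

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise PolynetError("n_pairs must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise PolynetError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_pairs:
            raise PolynetError("module_sizes sum exceeds n_pairs")
        for name in ("bias_fraction", "split_fraction", "rewire_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PolynetError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion < 0:
            raise PolynetError("dispersion must be >= 0")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise PolynetError("lib_size_range must be positive and ordered")
        if self.noise_sd < 0:
            raise PolynetError("noise_sd must be >= 0")
        if self.n_accessions < 1 or len(self.timepoints) < 1:
            raise PolynetError("need at least one accession and one timepoint")


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated dataset.

    ``gene_table`` (indexed by gene id, A copies then D copies) carries the
    per-gene planted state: pair id, subgenome, wild/domesticated module
    labels, baseline, loading, bias shift and rewiring flag.  Rewired genes
    keep their wild module label m but are recorded as ``m + n_modules`` in
    the domesticated column, marking the anti-correlated variant of the same
    module.  ``latent_profiles`` is modules x conditions; genes outside any
    module (label 0) follow their pair's private per-library profile from
    ``private_profiles``.
    """

    params: SimParams
    gene_table: pd.DataFrame
    latent_profiles: pd.DataFrame
    private_profiles: pd.DataFrame

    @property
    def pair_ids(self) -> pd.Index:
        a = self.gene_table[self.gene_table["subgenome"] == "A"]
        return pd.Index(a["pair_id"])

    @property
    def module_label_A(self) -> pd.Series:
        a = self.gene_table[self.gene_table["subgenome"] == "A"]
        return pd.Series(a["label_wild"].to_numpy(), index=a["pair_id"], name="label_A")

    @property
    def module_label_D(self) -> pd.Series:
        d = self.gene_table[self.gene_table["subgenome"] == "D"]
        return pd.Series(d["label_wild"].to_numpy(), index=d["pair_id"], name="label_D")

    @property
    def bias_class(self) -> pd.Series:
        a = self.gene_table[self.gene_table["subgenome"] == "A"]
        return pd.Series(a["bias_class"].to_numpy(), index=a["pair_id"], name="bias_class")

    @property
    def rewired_genes(self) -> pd.Index:
        return self.gene_table.index[self.gene_table["rewired"]]

    def dc_pair_set(self) -> set[tuple[str, str]]:
        """Unordered gene pairs whose wild/domesticated correlation differs
        by construction: same planted module, exactly one member rewired."""
        out: set[tuple[str, str]] = set()
        by_module: dict[int, pd.DataFrame] = {}
        tab = self.gene_table[self.gene_table["label_wild"] > 0]
        for m, sub in tab.groupby("label_wild"):
            genes = sub.index.to_numpy()
            rew = sub["rewired"].to_numpy()
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if rew[i] != rew[j]:
                        out.add(tuple(sorted((genes[i], genes[j]))))
        return out

    def pairing(self) -> HomoeologPairing:
        ids = self.pair_ids
        table = pd.DataFrame({
            "gene_A": [f"{p}_A" for p in ids],
            "gene_D": [f"{p}_D" for p in ids],
            "pair_id": list(ids),
        })
        return HomoeologPairing(table)


def make_sample_meta(params: SimParams) -> pd.DataFrame:
    """24-library design table: group x stage x accession."""
    rows = []
    for group in params.groups:
        prefix = "W" if group == "wild" else "D"
        for stage in params.timepoints:
            for r in range(1, params.n_accessions + 1):
                rows.append({
                    "sample": f"{group}_{stage}dpa_{prefix}{r}",
                    "accession": f"{prefix}{r}",
                    "group": group,
                    "stage_dpa": stage,
                })
    return pd.DataFrame(rows).set_index("sample")


#: log2-scale SD of module-level domestication offsets
GROUP_OFFSET_SD = 1.0


def _module_latent_profiles(k: int, timepoints, rng: np.random.Generator) -> np.ndarray:
    """k x 2T latent profiles over (wild stages | domesticated stages).

    Wild-group stage programs are zero-mean combinations of orthonormal
    stage polynomials forming a minimal-coherence frame; the domesticated
    programs are one shared rotation (timing shift) of the wild ones.
    Consequently every module has the same profile spread in both groups
    and every module pair has the same profile correlation in both groups
    — within-group coexpression is group-balanced by construction, which
    is what makes rewiring the only planted source of differential
    correlation.  Scaled so the per-condition RMS is LATENT_AMPLITUDE,
    then shifted in the domesticated half by a module-level N(0, 1) offset
    (domestication DE without any effect on correlations).
    """
    t = np.asarray(timepoints, dtype=float)
    T = len(t)
    J = T - 1
    if k > T:
        raise PolynetError(
            f"at most {T} planted modules are distinguishable over "
            f"{T} timepoints")
    vander = np.vander(t, T, increasing=True)[:, 1:]  # non-constant terms
    vander = vander - vander.mean(axis=0, keepdims=True)
    polys, _ = np.linalg.qr(vander)  # T x J, orthonormal, zero-mean
    # wild stage programs: a minimal-coherence frame in the zero-mean stage
    # space (orthonormal for k <= T-1; the regular simplex frame with
    # pairwise cosine -1/(k-1) for k == T), randomly rotated per seed
    rot, _ = np.linalg.qr(rng.normal(size=(J, J)))
    if k <= J:
        coords = rot[:k]
    else:
        A = np.eye(k) - 1.0 / k
        u, s, _ = np.linalg.svd(A)
        frame = u[:, :J]
        frame /= np.linalg.norm(frame, axis=1, keepdims=True)
        coords = frame @ rot
    # domesticated programs: one common rotation (a timing shift) of the
    # wild programs, so the two groups' profile Gram matrices — hence all
    # within-group gene-gene correlations — are identical by construction,
    # and rewiring stays the only planted correlation change
    timing, _ = np.linalg.qr(rng.normal(size=(J, J)))
    wild = coords @ polys.T
    dom = (coords @ timing) @ polys.T
    profiles = np.concatenate([wild, dom], axis=1) * LATENT_AMPLITUDE * np.sqrt(T)
    offsets = rng.normal(0.0, GROUP_OFFSET_SD, size=k)
    profiles[:, T:] += offsets[:, None]
    return profiles


def generate_truth(params: SimParams) -> GroundTruth:
    """Draw the planted structure.  Draw order (one generator, seed =
    params.seed): module latent profiles, per-pair private library
    profiles, baselines, loadings, split-pair choice + reassignment, bias
    choice + direction, rewired-gene choice."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    k = params.n_modules
    conditions = params.conditions

    # 1. module latent profiles (modules x group-stage conditions); see
    #    _module_latent_profiles for the group-balance guarantees
    latent = _module_latent_profiles(k, params.timepoints, rng)
    latent_profiles = pd.DataFrame(
        latent, index=pd.RangeIndex(1, k + 1, name="module"), columns=conditions)

    # base labels: contiguous blocks of pairs, remainder = background (0)
    labels = np.zeros(n, dtype=int)
    start = 0
    for m, size in enumerate(params.module_sizes, start=1):
        labels[start:start + size] = m
        start += size

    pair_ids = [f"g{i:05d}" for i in range(n)]
    genes = [f"{p}_A" for p in pair_ids] + [f"{p}_D" for p in pair_ids]
    label_a = labels.copy()
    label_d = labels.copy()

    # 2. private variation for background pairs: independent per library
    #    (no reproducible condition profile, hence no planted coexpression
    #    with other pairs), shared by the A and D copy of a pair so that
    #    the bias term stays the only systematic A/D difference
    sample_ids = make_sample_meta(params).index
    private = rng.normal(0.0, 1.0, size=(n, len(sample_ids))) * BACKGROUND_AMPLITUDE
    private_profiles = pd.DataFrame(np.vstack([private, private]),
                                    index=pd.Index(genes, name="gene"),
                                    columns=sample_ids)

    # 3. baseline and loading, shared by the two copies of a pair so that
    #    the planted bias term is the only systematic A/D difference
    baseline = np.tile(rng.uniform(*BASELINE_RANGE, size=n), 2)
    loading = np.tile(rng.uniform(*LOADING_RANGE, size=n), 2)

    # 4. co-module divergence: reassign the D copy of split pairs
    n_split = int(np.floor(params.split_fraction * n))
    split_idx = rng.choice(n, size=n_split, replace=False)
    for i in split_idx:
        current = label_d[i]
        candidates = [m for m in range(1, k + 1) if m != current]
        if not candidates:
            candidates = [0] if current != 0 else candidates
        if not candidates:  # single module and pair already background
            raise PolynetError("cannot split pairs with fewer than two modules")
        label_d[i] = candidates[int(rng.integers(len(candidates)))]

    # 5. homoeolog bias: symmetric +/- bias_lfc/2 per chosen pair
    n_bias = int(np.floor(params.bias_fraction * n))
    bias_idx = rng.choice(n, size=n_bias, replace=False)
    bias_class = np.array(["none"] * n, dtype=object)
    direction = rng.integers(0, 2, size=n_bias)  # 0 -> A-biased, 1 -> D-biased
    bias_class[bias_idx] = np.where(direction == 0, "A", "D")
    half = params.bias_lfc / 2.0
    shift_a = np.zeros(n)
    shift_a[bias_idx] = np.where(direction == 0, half, -half)
    shift = np.concatenate([shift_a, -shift_a])  # D copy gets the opposite sign

    # 6. rewiring: sign-flip loading in the domesticated group for a fraction
    #    of module-assigned genes (background genes have no module to leave)
    gene_labels_wild = np.concatenate([label_a, label_d])
    assigned = np.flatnonzero(gene_labels_wild > 0)
    n_rewire = int(np.floor(params.rewire_fraction * len(assigned)))
    rewired_idx = rng.choice(assigned, size=n_rewire, replace=False) if n_rewire else np.array([], dtype=int)
    rewired = np.zeros(2 * n, dtype=bool)
    rewired[rewired_idx] = True
    gene_labels_dom = gene_labels_wild.copy()
    gene_labels_dom[rewired] += k  # distinct domesticated-truth label

    gene_table = pd.DataFrame({
        "pair_id": pair_ids + pair_ids,
        "subgenome": ["A"] * n + ["D"] * n,
        "label_wild": gene_labels_wild,
        "label_dom": gene_labels_dom,
        "baseline": baseline,
        "loading": loading,
        "bias_shift": shift,
        "bias_class": np.concatenate([bias_class, bias_class]),
        "rewired": rewired,
    }, index=pd.Index(genes, name="gene"))

    return GroundTruth(params=params, gene_table=gene_table,
                       latent_profiles=latent_profiles,
                       private_profiles=private_profiles)


def simulate_counts(truth: GroundTruth, params: SimParams | None = None) -> CountMatrix:
    """Draw NB counts for the 2 x stages x accessions design.

    Per gene g and sample s with condition c: log2 mean = baseline_g +
    s_g * loading_g * latent(module_g, c) + bias_shift_g + log2(libfactor_s)
    + N(0, noise_sd), with s_g = -1 for rewired genes in domesticated
    samples.  Counts ~ NB(mu, dispersion) via gamma-Poisson; dispersion 0
    gives round(mu) exactly.  Uses its own generator seeded from
    params.seed so counts are reproducible given the truth.
    """
    if params is None:
        params = truth.params
    params.validate()
    rng = np.random.default_rng(np.uint32(params.seed) + np.uint32(1_000_003))
    meta = make_sample_meta(params)
    samples = meta.index
    n_samples = len(samples)
    tab = truth.gene_table
    n_genes = len(tab)
    conditions = [f"{g}_{t}" for g, t in zip(meta["group"], meta["stage_dpa"])]
    cond_pos = {c: i for i, c in enumerate(truth.latent_profiles.columns)}
    cond_idx = np.array([cond_pos[c] for c in conditions])
    is_dom = (meta["group"] == "domesticated").to_numpy()

    # latent activity per gene x sample
    activity = np.zeros((n_genes, n_samples))
    labels = tab["label_wild"].to_numpy()
    loadings = tab["loading"].to_numpy()
    rewired = tab["rewired"].to_numpy()
    latent = truth.latent_profiles.to_numpy()
    module_rows = labels > 0
    activity[module_rows] = latent[labels[module_rows] - 1][:, cond_idx]
    if (~module_rows).any():
        priv = truth.private_profiles.loc[tab.index[~module_rows], samples].to_numpy()
        activity[~module_rows] = priv
    sign = np.ones((n_genes, n_samples))
    sign[np.ix_(rewired, is_dom)] = -1.0

    lib = rng.uniform(*params.lib_size_range, size=n_samples)
    noise = (rng.normal(0.0, params.noise_sd, size=(n_genes, n_samples))
             if params.noise_sd > 0 else np.zeros((n_genes, n_samples)))

    log2_mu = (tab["baseline"].to_numpy()[:, None]
               + sign * loadings[:, None] * activity
               + tab["bias_shift"].to_numpy()[:, None]
               + np.log2(lib)[None, :]
               + noise)
    mu = np.exp2(log2_mu)

    phi = params.dispersion
    if phi == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam).astype(np.int64)

    df = pd.DataFrame(counts, index=tab.index, columns=samples)
    return CountMatrix(df, meta)


def simulate_dataset(params: SimParams) -> tuple[GroundTruth, CountMatrix, HomoeologPairing]:
    """Convenience: truth + counts + pairing in one call."""
    truth = generate_truth(params)
    counts = simulate_counts(truth, params)
    return truth, counts, truth.pairing()


# ---------------------------------------------------------------------------
# small fixture builders used by the preservation and DE calibration stages


def make_correlated_block(n_genes: int, n_samples: int, rho: float,
                          rng: np.random.Generator,
                          hub_range: float = 0.08,
                          shared: np.ndarray | None = None,
                          loadings: np.ndarray | None = None) -> np.ndarray:
    """Correlated Gaussian block around a shared factor: gene i is
    sqrt(r_i) * factor + sqrt(1 - r_i) * noise with r_i drawn uniformly in
    rho +/- hub_range, so pairwise correlations average ~rho while genes
    differ in how tightly they follow the factor — the intramodular
    hub-vs-periphery gradient real coexpression modules show.  Pass
    ``loadings`` (the per-gene r_i) to rebuild the same module in an
    independent dataset: preserved modules share loadings, not samples."""
    if shared is None:
        shared = rng.normal(size=n_samples)
    r = (np.asarray(loadings, dtype=float) if loadings is not None
         else rng.uniform(max(rho - hub_range, 0.0), min(rho + hub_range, 0.99),
                          size=n_genes))
    noise = rng.normal(size=(n_genes, n_samples))
    return np.sqrt(r)[:, None] * shared[None, :] + np.sqrt(1.0 - r)[:, None] * noise


def simulate_factorial_counts(n_genes: int, interaction_lfc: float = 0.0,
                              interaction_fraction: float = 1.0,
                              phi: float = 0.05, n_accessions: int = 3,
                              seed: int = 0) -> CountMatrix:
    """NB counts under the 2-group x 4-stage design with per-gene random
    main effects and an optional planted group:stage interaction.

    The interaction, when nonzero, adds ``interaction_lfc`` (log2) to the
    domesticated group at the last stage for the first
    ``floor(interaction_fraction * n_genes)`` genes, so exactly one
    interaction coefficient is nonzero per affected gene — a clean target
    for likelihood-ratio power checks.  Keep the fraction well below 1 in
    power studies: a shift shared by every gene is indistinguishable from
    a library-size change and is removed by normalization.
    ``interaction_lfc=0`` gives a null dataset for type-I calibration.
    """
    params = SimParams(n_pairs=1, n_accessions=n_accessions, seed=seed)
    meta = make_sample_meta(params)
    rng = np.random.default_rng(seed)
    n_samples = len(meta)
    stages = list(params.timepoints)
    baseline = rng.uniform(*BASELINE_RANGE, size=n_genes)
    group_eff = rng.normal(0.0, 0.5, size=n_genes)
    stage_eff = rng.normal(0.0, 0.5, size=(n_genes, len(stages)))
    stage_eff[:, 0] = 0.0

    is_dom = (meta["group"] == "domesticated").to_numpy()
    stage_idx = np.array([stages.index(s) for s in meta["stage_dpa"]])
    last = stage_idx == len(stages) - 1

    affected = np.arange(n_genes) < int(np.floor(interaction_fraction * n_genes))
    log2_mu = (baseline[:, None]
               + group_eff[:, None] * is_dom[None, :]
               + stage_eff[:, stage_idx]
               + interaction_lfc * affected[:, None] * (is_dom & last)[None, :])
    mu = np.exp2(log2_mu)
    if phi == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam).astype(np.int64)
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene")
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=meta.index), meta)
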