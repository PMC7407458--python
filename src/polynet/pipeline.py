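"""End-to-end orchestration.

Runs the full analysis on either simulated or user-supplied inputs:

1. data — simulate (or load) homoeolog counts, metadata, pairing;
2. filters & normalization — joint and homoeolog expression filters,
   median-of-ratios size factors, log transform;
3. differential expression — interaction LRT, domestication and stage
   contrasts, homoeolog-bias classification;
4. networks — joint (summed pairs), homoeologous (individual copies),
   wild-only and domesticated-only;
5. preservation — joint modules tested in the A and the D data, wild
   modules tested in the domesticated data;
6. homoeolog comparison — co-module fraction and the per-module bias table;
7. differential correlation — pair tests wild vs. domesticated and
   binomial DC genes;
8. enrichment — preranked GSEA of DE categories on each module's kME.

Every stage writes tab-separated tables under the output directory and a
``manifest.json`` records parameters, seeds and per-stage gene counts so a
run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (CountMatrix, ExpressionMatrix, HomoeologPairing, PolynetError,
                 filter_expressed, read_counts, read_pairing, size_factors,
                 sum_pairs, vst, write_counts, write_pairing)
from .simulate import SimParams, simulate_dataset
from .diffexpr import (DesignSpec, classify_bias, fit_nb_glm, lrt,
                       stack_homoeologs, wald_contrast)
from .network import NetworkParams, build_network, me_condition_anova
from .preservation import zsummary
from .homoeolog import co_module_fraction, module_bias_table
from .diffcorr import dc_genes, dc_pairs
from .enrichment import gsea_preranked

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    outdir: str = "polynet_out"
    seed: int = 0
    # either simulate...
    simulate: bool = True
    sim: SimParams = field(default_factory=SimParams)
    # ...or load from disk
    counts_path: str | None = None
    meta_path: str | None = None
    pairs_path: str | None = None
    # stage parameters
    network: NetworkParams = field(default_factory=NetworkParams)
    preservation_n_perm: int = 50
    dc_method: str = "bh"
    dc_threshold: float = 0.05
    dc_max_genes: int = 600
    enrichment_n_perm: int = 200
    alpha: float = 0.05

    def validate(self) -> None:
        if not self.simulate:
            for p in (self.counts_path, self.meta_path, self.pairs_path):
                if p is None or not Path(p).exists():
                    raise PolynetError(f"input file missing: {p}")


def load_config(path) -> PipelineConfig:
    """Read a flat YAML config with optional ``sim`` and ``network``
    sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimParams(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.pop("sim", {}).items()})
    network = NetworkParams(**raw.pop("network", {}))
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PolynetError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(sim=sim, network=network, **raw)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", **kw)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle (in-memory objects plus the
    manifest dict).  Raises a stage-named error on failure; tables written
    before the failure are retained."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    results: dict = {"manifest": manifest}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                info = fn() or {}
            except Exception as exc:  # pragma: no cover - error path
                raise PolynetError(f"stage {name!r} failed: {exc}") from exc
            info["seconds"] = round(time.time() - t0, 2)
            manifest["stages"][name] = info
            return info
        return deco

    # -- 1. data ----------------------------------------------------------
    @stage("data")
    def _data():
        if config.simulate:
            sim = SimParams(**{**asdict(config.sim), "seed": config.seed})
            truth, counts, pairing = simulate_dataset(sim)
            results["truth"] = truth
            info = {"simulated": True, "sim_params": asdict(sim)}
        else:
            counts = read_counts(config.counts_path, config.meta_path)
            pairing = read_pairing(config.pairs_path)
            info = {"simulated": False, "counts_path": config.counts_path}
        results["counts"] = counts
        results["pairing"] = pairing
        write_counts(counts, out / "counts.tsv", out / "sample_meta.tsv")
        write_pairing(pairing, out / "pairing.tsv")
        info.update(n_genes=len(counts.genes), n_samples=len(counts.samples),
                    n_pairs=len(pairing))
        return info

    counts: CountMatrix = results["counts"]
    pairing: HomoeologPairing = results["pairing"]

    # -- 2. filters & normalization --------------------------------------
    @stage("prepare")
    def _prepare():
        joint = sum_pairs(counts, pairing)
        joint_expressed = filter_expressed(joint, "joint")
        joint = joint.subset_genes(joint_expressed)
        homoeo_expressed = filter_expressed(counts, "homoeolog", pairing=pairing)
        homoeo = counts.subset_genes(homoeo_expressed)
        results["joint_counts"] = joint
        results["homoeo_counts"] = homoeo
        results["joint_expr"] = vst(joint)
        results["homoeo_expr"] = vst(homoeo)
        return {"pairs_expressed": len(joint_expressed),
                "homoeologs_expressed": len(homoeo_expressed)}

    joint_expr: ExpressionMatrix = results["joint_expr"]
    homoeo_expr: ExpressionMatrix = results["homoeo_expr"]
    homoeo_counts: CountMatrix = results["homoeo_counts"]

    # -- 3. differential expression ---------------------------------------
    @stage("diffexpr")
    def _de():
        design = DesignSpec(formula=("group", "stage_dpa", "group:stage_dpa"),
                            reduced=("group", "stage_dpa"))
        sf = size_factors(homoeo_counts)
        full = fit_nb_glm(homoeo_counts, design, factors=sf)
        reduced = fit_nb_glm(homoeo_counts, design, factors=sf,
                             dispersion=full.dispersion, terms=design.reduced)
        interaction = lrt(full, reduced)
        _write(interaction.table, out / "de_interaction_lrt.tsv", index_label="gene")
        dom = wald_contrast(reduced, "group", "domesticated", "wild")
        _write(dom.table, out / "de_domestication.tsv", index_label="gene")
        results["de_interaction"] = interaction
        results["de_domestication"] = dom

        stages = sorted(pd.unique(homoeo_counts.sample_meta["stage_dpa"]))
        stage_tables = {}
        for s1, s2 in zip(stages[1:], stages[:-1]):
            res = wald_contrast(full, "stage_dpa", s1, s2)
            stage_tables[f"{s1}v{s2}"] = res
            _write(res.table, out / f"de_stage_{s1}v{s2}.tsv", index_label="gene")
        results["de_stages"] = stage_tables

        # homoeolog bias: pairs kept by the homoeolog filter, A-vs-D contrast
        kept_pairs = pairing.table[
            pairing.table["gene_A"].isin(homoeo_counts.genes)
            & pairing.table["gene_D"].isin(homoeo_counts.genes)]
        bias_pairing = HomoeologPairing(kept_pairs.reset_index(drop=True))
        stacked = stack_homoeologs(counts, bias_pairing)
        bias_design = DesignSpec(formula=("subgenome", "group", "stage_dpa"))
        bias_fit = fit_nb_glm(stacked, bias_design)
        bias_res = wald_contrast(bias_fit, "subgenome", "A", "D")
        bias = classify_bias(bias_res, alpha=config.alpha)
        results["bias_classes"] = bias
        _write(bias.to_frame(), out / "bias_classes.tsv", index_label="pair_id")
        n_sig = int((interaction.table["padj"] < config.alpha).sum())
        return {"interaction_de": n_sig,
                "domestication_de": int((dom.table["padj"] < config.alpha).sum()),
                "biased_pairs": int((bias != "none").sum())}

    # -- 4. networks -------------------------------------------------------
    @stage("networks")
    def _networks():
        nets = {}
        nets["joint"] = build_network(joint_expr, config.network)
        nets["homoeologous"] = build_network(homoeo_expr, config.network)
        meta = homoeo_expr.sample_meta
        for grp in ("wild", "domesticated"):
            cols = meta.index[meta["group"] == grp]
            sub = ExpressionMatrix(homoeo_expr.values[list(cols)],
                                   provenance=homoeo_expr.provenance,
                                   sample_meta=meta.loc[cols])
            keep = sub.values.std(axis=1) > 0
            sub = ExpressionMatrix(sub.values[keep.to_numpy()],
                                   provenance=sub.provenance,
                                   sample_meta=sub.sample_meta)
            nets[grp] = build_network(sub, config.network)
        results["networks"] = nets
        info = {}
        for name, net in nets.items():
            _write(net.assignment.labels.to_frame(), out / f"modules_{name}.tsv",
                   index_label="gene")
            _write(net.eigengenes.values, out / f"eigengenes_{name}.tsv")
            _write(net.kme, out / f"kme_{name}.tsv", index_label="gene")
            info[name] = {"n_modules": len(net.eigengenes.modules),
                          "scale_free_index": round(net.scale_free_index, 3)}
        anova = me_condition_anova(nets["homoeologous"].eigengenes,
                                   homoeo_expr.sample_meta, alpha=config.alpha)
        _write(anova, out / "me_condition_anova.tsv")
        results["me_anova"] = anova
        return info

    nets = results["networks"]

    # -- 5. preservation ---------------------------------------------------
    @stage("preservation")
    def _preservation():
        info = {}
        joint_labels = nets["joint"].assignment.labels
        for sub, suffix in (("A", "_A"), ("D", "_D")):
            genes = [f"{p}{suffix}" for p in joint_labels.index]
            present = [g for g in genes if g in homoeo_expr.genes]
            sub_expr = ExpressionMatrix(
                homoeo_expr.values.loc[present].rename(
                    index=lambda g: g[:-2]),
                provenance=homoeo_expr.provenance,
                sample_meta=homoeo_expr.sample_meta)
            res = zsummary(joint_labels, joint_expr, sub_expr,
                           n_perm=config.preservation_n_perm,
                           seed=config.seed, beta=config.network.beta)
            _write(res.table, out / f"preservation_joint_vs_{sub}.tsv")
            results[f"preservation_{sub}"] = res
            info[f"joint_vs_{sub}_strong"] = int((res.table["class"] == "strong").sum())
        wild_labels = nets["wild"].assignment.labels
        res = zsummary(wild_labels, nets["wild"].expr, nets["domesticated"].expr,
                       n_perm=config.preservation_n_perm, seed=config.seed,
                       beta=config.network.beta)
        _write(res.table, out / "preservation_wild_vs_domesticated.tsv")
        results["preservation_wild_dom"] = res
        info["wild_vs_dom_strong"] = int((res.table["class"] == "strong").sum())
        return info

    # -- 6. homoeolog comparison ------------------------------------------
    @stage("homoeolog_comparison")
    def _homoeolog():
        labels = nets["homoeologous"].assignment.labels
        com = co_module_fraction(labels, labels, pairing)
        results["co_module"] = com
        bias_tab = module_bias_table(nets["joint"].assignment.labels,
                                     results["bias_classes"], alpha=config.alpha)
        results["bias_table"] = bias_tab
        _write(bias_tab, out / "module_bias_table.tsv")
        return {"co_module_fraction": round(com.fraction, 4) if np.isfinite(com.fraction) else None,
                "co_module_pairs": com.n_comodule}

    # -- 7. differential correlation --------------------------------------
    @stage("diffcorr")
    def _diffcorr():
        meta = homoeo_expr.sample_meta
        genes = homoeo_expr.genes
        if len(genes) > config.dc_max_genes:
            rng = np.random.default_rng(config.seed)
            genes = pd.Index(sorted(rng.choice(genes, config.dc_max_genes,
                                               replace=False)))
        sub = homoeo_expr.values.loc[genes]
        wild_cols = meta.index[meta["group"] == "wild"]
        dom_cols = meta.index[meta["group"] == "domesticated"]
        keep = (sub[list(wild_cols)].std(axis=1) > 0) & (sub[list(dom_cols)].std(axis=1) > 0)
        sub = sub[keep.to_numpy()]
        ew = ExpressionMatrix(sub[list(wild_cols)], sample_meta=meta.loc[wild_cols])
        ed = ExpressionMatrix(sub[list(dom_cols)], sample_meta=meta.loc[dom_cols])
        pairs = dc_pairs(ew, ed, threshold=config.dc_threshold,
                         method=config.dc_method)
        genes_res = dc_genes(pairs, alpha=config.alpha)
        results["dc_pairs"] = pairs
        results["dc_genes"] = genes_res
        _write(genes_res.table, out / "dc_genes.tsv", index_label="gene")
        _write(pairs.table.loc[pairs.table["significant"]],
               out / "dc_pairs_significant.tsv", index=False)
        return {"n_genes_tested": int(len(sub)),
                "n_pairs_significant": pairs.n_significant,
                "n_dc_genes": int(genes_res.table["dc_flag"].sum())}

    # -- 8. enrichment -----------------------------------------------------
    @stage("enrichment")
    def _enrichment():
        net = nets["homoeologous"]
        de_sets = {
            "domestication_DE": set(
                results["de_domestication"].table.index[
                    results["de_domestication"].table["padj"] < config.alpha]),
            "interaction_DE": set(
                results["de_interaction"].table.index[
                    results["de_interaction"].table["padj"] < config.alpha]),
        }
        de_sets = {k: v for k, v in de_sets.items() if len(v) >= 5}
        tables = []
        for m in net.eigengenes.modules:
            ranked = net.kme[m]
            if not de_sets:
                continue
            tab = gsea_preranked(ranked, de_sets,
                                 n_perm=config.enrichment_n_perm,
                                 seed=config.seed)
            if len(tab):
                tab = tab.reset_index()
                tab.insert(0, "module", m)
                tables.append(tab)
        if tables:
            enr = pd.concat(tables, ignore_index=True)
            _write(enr, out / "gsea_module_enrichment.tsv", index=False)
            results["enrichment"] = enr
            return {"n_tests": len(enr)}
        results["enrichment"] = pd.DataFrame()
        return {"n_tests": 0}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
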