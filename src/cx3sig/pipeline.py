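"""End-to-end orchestration of the RNA, protein and overlap workflows.

The RNA path: median-of-ratios normalization with floor at 1, present filter,
variable filter (feeding PCA and the heatmap table), then — on the present
genes — ANOVA differential expression, Markov clustering of the r >= 0.85
correlation graph, weighted correlation network analysis (power 7,
minModuleSize 30, eigengene-merge threshold 0.3), effector-cluster
selection, pre-signature construction, refinement and GO enrichment-map
construction. The protein path mirrors it with contaminant/valid-value
filtering, log2 transform, down-shifted-normal imputation, r >= 0.8, power
18 and merge threshold 0.5, and an absolute-difference-only refinement.

Every run produces a manifest (config snapshot, input digests, per-stage
in/out counts and durations) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, goea, io_formats, netclust, preprocess, signature
from .config import PipelineConfig
from .io_formats import CountMatrix, GeneSetCollection, IDMap, ProteinTable

logger = logging.getLogger("cx3sig.pipeline")


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, name: str, n_in: int, n_out: int, t0: float,
               **params) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise ValueError(f"stage {name!r} recorded twice")
        self.stages.append(
            {
                "stage": name,
                "n_in": int(n_in),
                "n_out": int(n_out),
                "params": params,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        logger.info("stage %s: %d -> %d", name, n_in, n_out)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str))


def digest_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(("\t".join(map(str, df.index)) + "\n").encode())
    h.update(("\t".join(map(str, df.columns)) + "\n").encode())
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


@dataclass
class RnaPipelineResult:
    normalized: preprocess.ExpressionMatrix
    present: preprocess.ExpressionMatrix
    variable: preprocess.ExpressionMatrix
    pca_scores: pd.DataFrame
    de: diffexpr.DEResult
    de_common: set[str]
    mcl_selected: frozenset[str]
    wcna_selected: frozenset[str]
    pre_signature: signature.SignatureSet
    refined_signature: signature.SignatureSet
    enrichment: goea.EnrichmentResult | None
    network: "object | None"
    manifest: RunManifest


def _group_mean_z(em: preprocess.ExpressionMatrix) -> pd.DataFrame:
    """Gene x population matrix of z-scored group means (z across samples)."""
    z = preprocess.z_transform(em)
    zem = preprocess.ExpressionMatrix(z, em.labels, scale="log2")
    return zem.group_means()


def run_rna_pipeline(config: PipelineConfig, cm: CountMatrix,
                     collection: GeneSetCollection | None = None,
                     out_dir: str | Path | None = None) -> RnaPipelineResult:
    """Full transcriptome workflow from raw counts to signature and GO map."""
    manifest = RunManifest(config=config.to_dict())
    manifest.input_digests["counts"] = digest_frame(cm.values)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    factors = preprocess.size_factors(cm)
    norm = preprocess.normalize_counts(cm, factors, floor=config.rna_floor)
    manifest.record("normalize", len(cm.values), len(norm.values), t0,
                    floor=config.rna_floor)

    t0 = time.perf_counter()
    present = preprocess.filter_present_rna(
        norm, min_mean=config.present_min_mean_count)
    manifest.record("present_filter", len(norm.values), len(present.values),
                    t0, min_mean=config.present_min_mean_count)

    t0 = time.perf_counter()
    variable = preprocess.filter_variable(present,
                                          alpha=config.variable_alpha)
    manifest.record("variable_filter", len(present.values),
                    len(variable.values), t0, alpha=config.variable_alpha)

    t0 = time.perf_counter()
    if len(variable.values) >= 2:
        zvar = preprocess.z_transform(variable)
        scores, _, _ = preprocess.pca(zvar)
    else:
        scores = pd.DataFrame(index=variable.values.columns)
    manifest.record("pca", len(variable.values), len(scores), t0)

    # downstream engines run on the present genes
    t0 = time.perf_counter()
    de = diffexpr.anova_de(present)
    de_common = diffexpr.common_upregulated(de, fc=config.de_fc,
                                            fdr=config.de_fdr)
    manifest.record("anova_de", len(present.values), len(de_common), t0,
                    fc=config.de_fc, fdr=config.de_fdr)

    gmz = _group_mean_z(present)

    t0 = time.perf_counter()
    graph = netclust.correlation_graph(present.values,
                                       min_r=config.mcl_min_r_rna)
    clusters = netclust.mcl(graph, inflation=config.mcl_inflation)
    if clusters.clusters:
        mcl_selected, mcl_score = netclust.select_effector_cluster(
            clusters.clusters, gmz)
    else:
        mcl_selected, mcl_score = frozenset(), float("nan")
    manifest.record("mcl", len(present.values), len(mcl_selected), t0,
                    min_r=config.mcl_min_r_rna,
                    inflation=config.mcl_inflation,
                    n_clusters=len(clusters.clusters), score=mcl_score)

    t0 = time.perf_counter()
    if len(present.values) >= config.wcna_min_module:
        modules = netclust.wcna(present.values, power=config.wcna_power_rna,
                                min_module=config.wcna_min_module,
                                mediss=config.wcna_mediss_rna)
        if modules.modules:
            wcna_selected, wcna_score = netclust.select_effector_cluster(
                modules.gene_sets(), gmz)
        else:
            wcna_selected, wcna_score = frozenset(), float("nan")
        n_modules = len(modules.modules)
    else:
        wcna_selected, wcna_score, n_modules = frozenset(), float("nan"), 0
    manifest.record("wcna", len(present.values), len(wcna_selected), t0,
                    power=config.wcna_power_rna,
                    min_module=config.wcna_min_module,
                    mediss=config.wcna_mediss_rna,
                    n_modules=n_modules, score=wcna_score)

    t0 = time.perf_counter()
    pre = signature.derive_pre_signature(de_common, set(mcl_selected),
                                         set(wcna_selected), omics="rna")
    manifest.record("pre_signature", len(de_common), len(pre), t0)

    t0 = time.perf_counter()
    refined = signature.refine_signature(
        pre, present, fc_min=config.refine_fc,
        abs_diff_min=config.refine_abs_diff_rna,
        blocklist=config.mhc2_blocklist, rule=config.refine_rule)
    if config.subtract_cx3cr1n_enriched:
        neg_up = diffexpr.common_upregulated(
            diffexpr.anova_de(present,
                              contrasts=list(diffexpr.CX3CR1N_VS_NAIVE)),
            fc=config.de_fc, fdr=config.de_fdr,
            contrasts=list(diffexpr.CX3CR1N_VS_NAIVE))
        refined = signature.subtract_genes(refined, neg_up)
    manifest.record("refine", len(pre), len(refined), t0,
                    fc_min=config.refine_fc,
                    abs_diff_min=config.refine_abs_diff_rna,
                    rule=config.refine_rule,
                    subtract_cx3cr1n=config.subtract_cx3cr1n_enriched)

    enrichment = None
    network = None
    if collection is not None and len(refined) > 0:
        t0 = time.perf_counter()
        universe = set(present.gene_ids)
        enrichment = goea.hypergeom_enrich(
            set(refined.genes) & universe, universe, collection)
        network = goea.enrichment_map(enrichment,
                                      jaccard_min=config.map_jaccard,
                                      q_cutoff=config.map_q)
        manifest.record("goea", len(enrichment.table),
                        network.number_of_nodes(), t0,
                        fdr=config.goea_fdr, jaccard=config.map_jaccard,
                        q=config.map_q)

    if out is not None:
        io_formats.write_signature(pre, out / "pre_signature.tsv")
        io_formats.write_signature(refined, out / "refined_signature.tsv")
        de.to_frame().to_csv(out / "de.tsv", sep="\t", index_label="gene")
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
        if network is not None:
            io_formats.write_network(network, out / "go_nodes.tsv",
                                     out / "go_edges.tsv")
        manifest.to_json(out / "manifest.json")
        manifest.outputs = {p.name: str(p) for p in out.iterdir()}

    return RnaPipelineResult(
        normalized=norm, present=present, variable=variable,
        pca_scores=scores, de=de, de_common=de_common,
        mcl_selected=frozenset(mcl_selected),
        wcna_selected=frozenset(wcna_selected),
        pre_signature=pre, refined_signature=refined,
        enrichment=enrichment, network=network, manifest=manifest,
    )


@dataclass
class ProteinPipelineResult:
    filtered: preprocess.ExpressionMatrix      # log2, NaN preserved
    imputed: preprocess.ExpressionMatrix       # log2, complete
    linear: preprocess.ExpressionMatrix        # imputed, linear scale
    de: diffexpr.DEResult
    de_common: set[str]
    mcl_selected: frozenset[str]
    wcna_selected: frozenset[str]
    pre_signature: signature.SignatureSet
    refined_signature: signature.SignatureSet
    manifest: RunManifest


def run_protein_pipeline(config: PipelineConfig, pt: ProteinTable,
                         out_dir: str | Path | None = None
                         ) -> ProteinPipelineResult:
    """Proteome workflow: filter, impute, cluster, signature, refine."""
    manifest = RunManifest(config=config.to_dict())
    manifest.input_digests["protein"] = digest_frame(
        pt.intensities.fillna(0.0))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    filtered = preprocess.filter_proteins(pt,
                                          min_valid=config.protein_min_valid)
    manifest.record("protein_filter", len(pt.intensities),
                    len(filtered.values), t0,
                    min_valid=config.protein_min_valid)

    t0 = time.perf_counter()
    imputed = preprocess.impute_missing(
        filtered, shift=config.impute_shift, width=config.impute_width,
        seed=config.rng_seed, global_distribution=config.impute_global)
    manifest.record("impute", len(filtered.values), len(imputed.values), t0,
                    shift=config.impute_shift, width=config.impute_width)

    linear = preprocess.ExpressionMatrix(
        np.power(2.0, imputed.values), imputed.labels,
        scale="normalized_counts")

    t0 = time.perf_counter()
    de = diffexpr.anova_de(linear)
    de_common = diffexpr.common_upregulated(de, fc=config.de_fc,
                                            fdr=config.de_fdr)
    manifest.record("anova_de", len(linear.values), len(de_common), t0)

    gmz = _group_mean_z(imputed)

    t0 = time.perf_counter()
    graph = netclust.correlation_graph(imputed.values,
                                       min_r=config.mcl_min_r_protein)
    clusters = netclust.mcl(graph, inflation=config.mcl_inflation)
    if clusters.clusters:
        mcl_selected, _ = netclust.select_effector_cluster(
            clusters.clusters, gmz)
    else:
        mcl_selected = frozenset()
    manifest.record("mcl", len(imputed.values), len(mcl_selected), t0,
                    min_r=config.mcl_min_r_protein,
                    n_clusters=len(clusters.clusters))

    t0 = time.perf_counter()
    if len(imputed.values) >= config.wcna_min_module:
        modules = netclust.wcna(imputed.values,
                                power=config.wcna_power_protein,
                                min_module=config.wcna_min_module,
                                mediss=config.wcna_mediss_protein)
        if modules.modules:
            wcna_selected, _ = netclust.select_effector_cluster(
                modules.gene_sets(), gmz)
        else:
            wcna_selected = frozenset()
        n_modules = len(modules.modules)
    else:
        wcna_selected, n_modules = frozenset(), 0
    manifest.record("wcna", len(imputed.values), len(wcna_selected), t0,
                    power=config.wcna_power_protein,
                    mediss=config.wcna_mediss_protein, n_modules=n_modules)

    t0 = time.perf_counter()
    pre = signature.derive_pre_signature(de_common, set(mcl_selected),
                                         set(wcna_selected), omics="protein")
    manifest.record("pre_signature", len(de_common), len(pre), t0)

    t0 = time.perf_counter()
    refined = signature.refine_protein_signature(
        pre, linear, abs_diff_min=config.refine_abs_diff_protein,
        blocklist=config.mhc2_blocklist)
    manifest.record("refine", len(pre), len(refined), t0,
                    abs_diff_min=config.refine_abs_diff_protein)

    if out is not None:
        io_formats.write_signature(pre, out / "protein_pre_signature.tsv")
        io_formats.write_signature(refined,
                                   out / "protein_refined_signature.tsv")
        manifest.to_json(out / "protein_manifest.json")

    return ProteinPipelineResult(
        filtered=filtered, imputed=imputed, linear=linear, de=de,
        de_common=de_common, mcl_selected=frozenset(mcl_selected),
        wcna_selected=frozenset(wcna_selected), pre_signature=pre,
        refined_signature=refined, manifest=manifest,
    )


@dataclass
class OverlapResult:
    overlap: set[str]
    detected_count: int
    detected_genes: list[str]
    rna_rank_table: pd.DataFrame
    rna_discordant: int
    manifest: RunManifest


def run_overlap(config: PipelineConfig, rna: RnaPipelineResult,
                prot: ProteinPipelineResult, idmap: IDMap,
                out_dir: str | Path | None = None) -> OverlapResult:
    """Cross-omics overlap and concordance report."""
    manifest = RunManifest(config=config.to_dict())
    t0 = time.perf_counter()
    overlap = signature.overlap_signatures(rna.refined_signature,
                                           prot.refined_signature, idmap)
    manifest.record("overlap", len(rna.refined_signature), len(overlap), t0)

    t0 = time.perf_counter()
    count, detected = signature.detected_in_proteome(
        rna.refined_signature, prot.filtered, idmap)
    manifest.record("detected_in_proteome", len(rna.refined_signature),
                    count, t0)

    # fold-change rank concordance: RNA signature genes vs their proteins
    t0 = time.perf_counter()
    match = signature.match_omics(prot.filtered, idmap)
    prot_pooled_pos, prot_pooled_neg = signature._pooled_cx3cr1_means(
        prot.linear, list(prot.linear.values.index))
    prot_log2fc_by_gene = pd.Series(
        {g: float(np.log2(prot_pooled_pos[a] / prot_pooled_neg[a]))
         for g, a in match.pairs.items() if a in prot_pooled_pos.index}
    )
    rna_genes = rna.refined_signature.genes
    if rna_genes:
        rna_pos, rna_neg = signature._pooled_cx3cr1_means(
            rna.present, rna_genes)
        rna_log2fc = np.log2(rna_pos / rna_neg)
        rank_table, discordant = diffexpr.fold_change_rank(
            rna_log2fc, prot_log2fc_by_gene)
    else:
        rank_table, discordant = pd.DataFrame(), 0
    manifest.record("fold_change_rank", len(rna_genes), discordant, t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.Series(sorted(overlap)).to_csv(out / "overlap_genes.tsv",
                                          sep="\t", index=False,
                                          header=["gene"])
        rank_table.to_csv(out / "fold_change_rank.tsv", sep="\t",
                          index_label="gene")
        manifest.to_json(out / "overlap_manifest.json")

    return OverlapResult(
        overlap=overlap, detected_count=count, detected_genes=detected,
        rna_rank_table=rank_table, rna_discordant=discordant,
        manifest=manifest,
    )
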