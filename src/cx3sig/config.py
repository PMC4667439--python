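"""Pipeline configuration.

Every tunable threshold of the signature-derivation workflow lives here, with
defaults equal to the published values: the microarray background intensity,
the SOM geometry, the RNA-seq present/variable filters, the ANOVA DE cutoffs,
the MCL / weighted-correlation-network parameters for both omics layers, the
signature refinement rules, the proteome valid-value and imputation settings,
and the GO-enrichment / enrichment-map cutoffs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Classical polymorphic HLA class II loci, removed from refined signatures.
#: User-supplied blocklists override this default.
DEFAULT_MHC2_BLOCKLIST: tuple[str, ...] = (
    "HLA-DRA", "HLA-DRB1", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5",
    "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DQB2",
    "HLA-DPA1", "HLA-DPB1",
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
)


@dataclass
class PipelineConfig:
    """All thresholds of the consensus-signature pipeline.

    Attributes
    ----------
    microarray_background
        log2-intensity background; probesets with every group mean below this
        are dropped from microarray data.
    som_clusters, som_iterations
        Self-organizing-map size (units) and online-training iterations.
    rna_floor
        Normalized read counts below this are raised to it, avoiding spurious
        fold changes from near-zero denominators.
    present_min_mean_count
        RNA-seq present filter: a gene is present when its mean normalized
        count exceeds this in at least one population.
    variable_alpha
        Unadjusted one-way ANOVA p-value cutoff for the "variable" filter.
    de_fc, de_fdr
        Differential-expression thresholds: fold change and BH-adjusted p.
    mcl_min_r_rna, mcl_min_r_protein
        Pearson-correlation edge thresholds for the MCL graph.
    mcl_inflation
        MCL inflation exponent (the algorithm's customary default).
    wcna_power_rna, wcna_power_protein
        Soft-thresholding powers for the weighted correlation network.
    wcna_min_module
        Minimum module size; smaller branches go to the unassigned pool.
    wcna_mediss_rna, wcna_mediss_protein
        Module-eigengene dissimilarity (1 - cor) below which modules merge.
    refine_fc, refine_abs_diff_rna, refine_abs_diff_protein
        Signature refinement: CX3CR1+ vs CX3CR1- pooled-mean fold-change and
        absolute-difference cutoffs (RNA on normalized counts, protein on
        linear intensity).
    refine_rule
        "AND" removes a gene only when both refinement criteria fail;
        "OR" removes when either fails.
    subtract_cx3cr1n_enriched
        Optionally also remove pre-signature genes significantly upregulated
        in both CX3CR1- populations versus naive. Off by default: signature
        genes are expected to show intermediate CX3CR1- expression, and the
        CX3CR1+ vs CX3CR1- refinement already removes genes without a
        CX3CR1+ excess.
    mhc2_blocklist
        Gene symbols excluded from refined signatures.
    protein_min_valid
        Minimum valid LFQ quantifications required in at least one group.
    impute_shift, impute_width
        Down-shifted normal imputation: missing log2 intensities are drawn
        from Normal(mu - shift*sigma, (width*sigma)^2) per sample column.
    impute_global
        Impute from the global observed distribution instead of per column.
    goea_fdr
        BH q cutoff for reporting enriched GO terms.
    map_jaccard, map_q
        Enrichment-map edge (Jaccard) and node (q) cutoffs.
    rng_seed
        Master seed; stage-scoped substreams are derived from it.
    """

    microarray_background: float = 6.7886
    som_clusters: int = 25
    som_iterations: int = 20000
    rna_floor: float = 1.0
    present_min_mean_count: float = 10.0
    variable_alpha: float = 0.05
    de_fc: float = 2.0
    de_fdr: float = 0.05
    mcl_min_r_rna: float = 0.85
    mcl_min_r_protein: float = 0.8
    mcl_inflation: float = 2.2
    wcna_power_rna: float = 7.0
    wcna_power_protein: float = 18.0
    wcna_min_module: int = 30
    wcna_mediss_rna: float = 0.3
    wcna_mediss_protein: float = 0.5
    refine_fc: float = 1.5
    refine_abs_diff_rna: float = 50.0
    refine_abs_diff_protein: float = 1e6
    refine_rule: str = "AND"
    subtract_cx3cr1n_enriched: bool = False
    mhc2_blocklist: tuple[str, ...] = DEFAULT_MHC2_BLOCKLIST
    protein_min_valid: int = 3
    impute_shift: float = 1.8
    impute_width: float = 0.3
    impute_global: bool = False
    goea_fdr: float = 0.05
    map_jaccard: float = 0.25
    map_q: float = 0.025
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "microarray_background", "som_clusters", "som_iterations",
            "rna_floor", "present_min_mean_count", "de_fc", "de_fdr",
            "mcl_min_r_rna", "mcl_min_r_protein", "mcl_inflation",
            "wcna_power_rna", "wcna_power_protein", "wcna_min_module",
            "wcna_mediss_rna", "wcna_mediss_protein", "refine_fc",
            "refine_abs_diff_rna", "refine_abs_diff_protein",
            "protein_min_valid", "impute_shift", "impute_width",
            "goea_fdr", "map_jaccard", "map_q",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not 0 <= self.variable_alpha <= 1:
            raise ValueError("variable_alpha must lie in [0, 1]")
        if self.refine_rule not in ("AND", "OR"):
            raise ValueError("refine_rule must be 'AND' or 'OR'")
        self.mhc2_blocklist = tuple(self.mhc2_blocklist)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mhc2_blocklist"] = list(d["mhc2_blocklist"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
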