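"""Consensus signature logic.

The pre-signature is the union of two intersections: (selected MCL cluster ∩
commonly upregulated genes) and (selected network module ∩ commonly
upregulated genes). Refinement removes genes whose pooled CX3CR1+ vs CX3CR1-
fold change and absolute expression difference both fall below their cutoffs
(conjunctive by default, configurable to disjunctive), then strips known
polymorphic MHC class II genes. The proteome signature is refined on the
absolute linear-intensity difference only. Cross-omics operations map
protein accessions to gene symbols and compute the signature overlap, the
detected-in-proteome count, the fold-change-rank concordance and the
expression-class histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CX3CR1_NEGATIVE,
    CX3CR1_POSITIVE,
    IDMap,
    ProteinTable,
)
from .preprocess import ExpressionMatrix

logger = logging.getLogger("cx3sig.signature")

#: Provenance tags for signature members.
PROV_DE_MCL = "DE∩MCL"
PROV_DE_WCNA = "DE∩WCNA"


@dataclass
class SignatureSet:
    """Ordered signature gene list with per-gene provenance.

    ``stage`` is ``"pre"`` or ``"refined"``; ``omics`` is ``"rna"`` or
    ``"protein"``. Every member carries a non-empty provenance set.
    """

    genes: list[str]
    provenance: dict[str, frozenset[str]]
    stage: str = "pre"
    omics: str = "rna"

    def __post_init__(self) -> None:
        if self.stage not in ("pre", "refined"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.omics not in ("rna", "protein"):
            raise ValueError(f"unknown omics {self.omics!r}")
        for g in self.genes:
            if not self.provenance.get(g):
                raise ValueError(f"signature gene {g!r} lacks provenance")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance and gene in set(self.genes)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def restrict(self, keep: set[str], stage: str | None = None
                 ) -> "SignatureSet":
        genes = [g for g in self.genes if g in keep]
        return SignatureSet(
            genes=genes,
            provenance={g: self.provenance[g] for g in genes},
            stage=stage or self.stage,
            omics=self.omics,
        )


def derive_pre_signature(de_common: set[str], mcl_selected: set[str],
                         wcna_selected: set[str],
                         omics: str = "rna") -> SignatureSet:
    """Union of the two cluster ∩ DE intersections, with provenance."""
    members: dict[str, set[str]] = {}
    for g in mcl_selected & de_common:
        members.setdefault(g, set()).add(PROV_DE_MCL)
    for g in wcna_selected & de_common:
        members.setdefault(g, set()).add(PROV_DE_WCNA)
    genes = sorted(members)
    return SignatureSet(
        genes=genes,
        provenance={g: frozenset(tags) for g, tags in members.items()},
        stage="pre",
        omics=omics,
    )


def _pooled_cx3cr1_means(em: ExpressionMatrix, genes: list[str]
                         ) -> tuple[pd.Series, pd.Series]:
    """Mean over all CX3CR1+ samples and all CX3CR1- samples per gene."""
    pos_cols = [s for s in em.values.columns
                if em.labels[s] in CX3CR1_POSITIVE]
    neg_cols = [s for s in em.values.columns
                if em.labels[s] in CX3CR1_NEGATIVE]
    if not pos_cols or not neg_cols:
        raise ValueError("both CX3CR1+ and CX3CR1- samples are required")
    sub = em.values.loc[genes]
    return sub[pos_cols].mean(axis=1), sub[neg_cols].mean(axis=1)


def refine_signature(pre: SignatureSet, em: ExpressionMatrix,
                     fc_min: float = 1.5, abs_diff_min: float = 50.0,
                     blocklist: tuple[str, ...] = (),
                     rule: str = "AND") -> SignatureSet:
    """CX3CR1+ vs CX3CR1- refinement of the RNA pre-signature.

    Fold change and absolute difference are computed between the pooled mean
    of the two CX3CR1+ populations and the pooled mean of the two CX3CR1-
    populations. Under ``rule="AND"`` a gene is removed when FC < fc_min AND
    |diff| < abs_diff_min; under ``"OR"`` when either criterion fails.
    Blocklisted genes are removed last.
    """
    missing = [g for g in pre.genes if g not in em.values.index]
    if missing:
        raise ValueError(f"pre-signature genes absent from expression matrix: "
                         f"{missing[:10]}")
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    pos, neg = _pooled_cx3cr1_means(em, pre.genes)
    fc = pos / neg
    diff = (pos - neg).abs()
    low_fc = fc < fc_min
    low_diff = diff < abs_diff_min
    removed = (low_fc & low_diff) if rule == "AND" else (low_fc | low_diff)
    keep = set(fc.index[~removed]) - set(blocklist)
    logger.info("refine (rna): %d -> %d genes (%d below thresholds, "
                "%d blocklisted)", len(pre), len(keep & set(pre.genes)),
                int(removed.sum()),
                len(set(pre.genes) & set(blocklist) - set(fc.index[removed])))
    return pre.restrict(keep, stage="refined")


def refine_protein_signature(pre: SignatureSet, em_linear: ExpressionMatrix,
                             abs_diff_min: float = 1e6,
                             blocklist: tuple[str, ...] = ()) -> SignatureSet:
    """Proteome refinement: absolute linear-intensity difference only.

    ``em_linear`` must hold linear-scale intensities (imputed log2 matrices
    are converted by the pipeline before calling this).
    """
    missing = [g for g in pre.genes if g not in em_linear.values.index]
    if missing:
        raise ValueError(f"pre-signature proteins absent from matrix: "
                         f"{missing[:10]}")
    pos, neg = _pooled_cx3cr1_means(em_linear, pre.genes)
    diff = (pos - neg).abs()
    keep = set(diff.index[diff >= abs_diff_min]) - set(blocklist)
    logger.info("refine (protein): %d -> %d", len(pre),
                len(keep & set(pre.genes)))
    return pre.restrict(keep, stage="refined")


def subtract_genes(sig: SignatureSet, exclude: set[str]) -> SignatureSet:
    """Remove an explicit exclusion set (e.g. genes also enriched in the
    CX3CR1-negative populations) from a signature, preserving stage."""
    return sig.restrict(sig.gene_set() - exclude)


# ---------------------------------------------------------------------------
# cross-omics matching
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatch:
    """Accession -> gene matching result.

    ``pairs`` maps gene symbol -> chosen accession; ``unmatched`` lists
    accessions without a mapping.
    """

    pairs: dict[str, str]
    unmatched: list[str]


def match_omics(protein_table: ProteinTable | ExpressionMatrix,
                idmap: IDMap) -> OmicsMatch:
    """Map protein rows to gene symbols; resolve many-to-one by the highest
    mean intensity (logged)."""
    if isinstance(protein_table, ProteinTable):
        inten = protein_table.intensities
    else:
        inten = protein_table.values
    mean_int = inten.mean(axis=1, skipna=True)
    best: dict[str, tuple[float, str]] = {}
    unmatched: list[str] = []
    for acc in inten.index:
        sym = idmap.get(acc)
        if sym is None:
            unmatched.append(acc)
            continue
        score = float(mean_int[acc]) if np.isfinite(mean_int[acc]) else -np.inf
        if sym not in best or score > best[sym][0]:
            if sym in best:
                logger.info("gene %s: accession %s supersedes %s "
                            "(higher mean intensity)", sym, acc, best[sym][1])
            best[sym] = (score, acc)
    if unmatched:
        logger.info("%d accessions had no gene mapping", len(unmatched))
    return OmicsMatch(pairs={s: a for s, (_, a) in best.items()},
                      unmatched=unmatched)


def overlap_signatures(rna_sig: SignatureSet, prot_sig: SignatureSet,
                       idmap: IDMap) -> set[str]:
    """Refined RNA signature ∩ gene-mapped refined protein signature."""
    prot_genes = set()
    for acc in prot_sig.genes:
        sym = idmap.get(acc)
        prot_genes.add(sym if sym is not None else acc)
    return rna_sig.gene_set() & prot_genes


def detected_in_proteome(rna_sig: SignatureSet,
                         protein_em: ExpressionMatrix | ProteinTable,
                         idmap: IDMap) -> tuple[int, list[str]]:
    """Signature genes with at least one matched, filter-surviving protein
    row. ``protein_em`` should be the post-filter protein matrix."""
    match = match_omics(protein_em, idmap)
    detected = [g for g in rna_sig.genes if g in match.pairs]
    return len(detected), detected


def expression_class_histogram(rna_em: ExpressionMatrix,
                               protein_em_log2: ExpressionMatrix,
                               idmap: IDMap, n_classes: int = 5,
                               n_bins: int = 20) -> pd.DataFrame:
    """Histograms of log-scale RNA expression by protein-abundance class.

    Present genes are binned by their matched protein's mean log2 intensity
    into ``n_classes`` equal-width classes; genes without a matched protein
    form the separate class ``"unmatched"``. Returns a tidy frame with
    columns (class, bin_left, bin_right, count); counts sum to the number of
    present genes.
    """
    match = match_omics(protein_em_log2, idmap)
    mean_prot = protein_em_log2.values.mean(axis=1)
    gene_prot = pd.Series(
        {g: float(mean_prot[acc]) for g, acc in match.pairs.items()
         if acc in mean_prot.index}
    )
    rna = np.log10(rna_em.values.mean(axis=1))
    classes = pd.Series("unmatched", index=rna.index, dtype=object)
    matched = rna.index.intersection(gene_prot.index)
    if len(matched) > 0:
        lo, hi = gene_prot[matched].min(), gene_prot[matched].max()
        edges = np.linspace(lo, hi, n_classes + 1)
        edges[-1] += 1e-9
        which = np.digitize(gene_prot[matched], edges) - 1
        which = np.clip(which, 0, n_classes - 1)
        classes[matched] = [f"class_{w + 1}" for w in which]
    bins = np.histogram_bin_edges(rna, bins=n_bins)
    rows = []
    for cls, members in rna.groupby(classes):
        counts, _ = np.histogram(members, bins=bins)
        for left, right, count in zip(bins[:-1], bins[1:], counts):
            rows.append((cls, left, right, int(count)))
    return pd.DataFrame(rows,
                        columns=["class", "bin_left", "bin_right", "count"])
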