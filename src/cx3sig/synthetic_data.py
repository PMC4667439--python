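"""Synthetic multi-omics data with planted structure.

The generator emulates the study design the pipeline assumes: five sorted
CD8+ T-cell populations with biological replicates, a planted block of
effector-signature genes that is high in both CX3CR1+ populations,
moderate in the CX3CR1- populations and low in naive cells, co-regulated
background modules driven by shared latent factors, negative-binomial read
counts with sample-specific library sizes, log-normally distributed
label-free protein intensities coupled to the RNA level, a
missing-not-at-random dropout mechanism concentrated at low abundance, and a
gene-set collection whose planted terms are enriched among signature genes.
Every output is a deterministic function of the seed.

Defaults are the study conditions used throughout the test suite and the
reproduction script: 5000 genes, 200 planted signature genes, 3 background
modules of 50 genes, 5 replicates per population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ALL_POPULATIONS,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    IDMap,
    PopulationLabel,
    ProteinTable,
)

#: Planted mean multipliers for the moderate (CX3CR1-) and reference (naive)
#: populations; the CX3CR1+ effector strength is drawn per gene.
CX3CR1N_MULTIPLIER = 2.0
NAIVE_MULTIPLIER = 1.0
#: Per-gene CX3CR1+ effector strength: log-uniform over this range, shared
#: between the two CX3CR1+ populations. The gene-to-gene spread mirrors the
#: wide fold-change spectrum of real effector programs and is what puts
#: signature genes on the diagonal of the two CX3CR1+ vs naive contrasts.
EFFECT_RANGE = (4.0, 64.0)

NB_DISPERSION = 0.1          #: var = mu + d * mu^2
BASE_MEAN_RANGE = (5.0, 5000.0)
LIBSIZE_SDLOG = 0.3
MODULE_FACTOR_SD = 1.5       #: latent-factor strength of background modules
SIGNATURE_FACTOR_SD = 0.25   #: weak shared factor of the effector program
PROTEIN_INTERCEPT = 20.0     #: log2 intensity at log2(RNA mean) = 0
PROTEIN_SLOPE = 1.0
PROTEIN_NOISE_SD = 0.5
MISSING_MIDPOINT = 24.0      #: log2 intensity of 50% dropout
MISSING_SCALE = 1.5
CONTAMINANT_FRAC = 0.02


@dataclass
class GroundTruth:
    """What was planted: signature genes, module memberships, effect sizes,
    enriched annotation terms."""

    signature_genes: frozenset[str]
    module_map: dict[str, int]          # gene -> module id, 0 = background
    effect: dict[str, dict[str, float]]  # gene -> population -> multiplier
    enriched_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for g in self.signature_genes:
            e = self.effect[g]
            pos = min(e[p.value] for p in (PopulationLabel.CX3CR1P_CD62LHI,
                                           PopulationLabel.CX3CR1P_CD62LLO))
            neg = max(e[p.value] for p in (PopulationLabel.CX3CR1N_CD62LHI,
                                           PopulationLabel.CX3CR1N_CD62LLO))
            naive = e[PopulationLabel.NAIVE.value]
            if not (pos > neg >= naive):
                raise ValueError(f"planted effect direction violated for {g}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + d*mu^2 via gamma-Poisson."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_rna(n_genes: int = 5000, n_sig: int = 200, n_modules: int = 3,
                 reps_per_group: int = 5, seed: int = 0,
                 module_size: int = 50) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the five-population RNA-seq count matrix.

    Counts are negative binomial (dispersion 0.1) around gene base means
    drawn log-uniformly over [5, 5000], scaled by sample library-size
    factors (log-normal, sdlog 0.3). Signature genes carry a per-gene
    effector strength (log-uniform over [4, 64], identical in both CX3CR1+
    populations) against multipliers 2 in the CX3CR1- populations and 1 in
    naive cells, plus a weak shared latent factor (the effector program is
    itself co-regulated); each background module shares a strong per-sample
    latent factor inducing high within-module correlation.
    """
    if reps_per_group < 2:
        raise ValueError("reps_per_group must be >= 2")
    if n_sig >= n_genes:
        raise ValueError("n_sig must be smaller than n_genes")
    if n_sig + n_modules * module_size > n_genes:
        raise ValueError(
            f"impossible partition: {n_sig} signature + {n_modules} x "
            f"{module_size} module genes exceed {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = []
    labels: dict[str, PopulationLabel] = {}
    for pop in ALL_POPULATIONS:
        for r in range(reps_per_group):
            s = f"{pop.value}_r{r + 1}"
            samples.append(s)
            labels[s] = pop
    n_samples = len(samples)

    sig_genes = genes[:n_sig]
    module_map: dict[str, int] = {g: 0 for g in genes}
    module_genes: list[list[str]] = []
    offset = n_sig
    for m in range(n_modules):
        block = genes[offset:offset + module_size]
        module_genes.append(block)
        for g in block:
            module_map[g] = m + 1
        offset += module_size

    lo, hi = BASE_MEAN_RANGE
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    libsize = np.exp(rng.normal(0.0, LIBSIZE_SDLOG, size=n_samples))

    lo_e, hi_e = EFFECT_RANGE
    strength = np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), size=n_sig))
    pop_mult = {
        PopulationLabel.CX3CR1P_CD62LHI: strength,
        PopulationLabel.CX3CR1P_CD62LLO: strength,
        PopulationLabel.CX3CR1N_CD62LHI: np.full(n_sig, CX3CR1N_MULTIPLIER),
        PopulationLabel.CX3CR1N_CD62LLO: np.full(n_sig, CX3CR1N_MULTIPLIER),
        PopulationLabel.NAIVE: np.full(n_sig, NAIVE_MULTIPLIER),
    }
    mult = np.ones((n_genes, n_samples))
    for j, s in enumerate(samples):
        mult[:n_sig, j] = pop_mult[labels[s]]

    # shared latent factors (per-sample, log-normal)
    sig_factor = np.exp(rng.normal(0.0, SIGNATURE_FACTOR_SD, size=n_samples)
                        - SIGNATURE_FACTOR_SD**2 / 2)
    mult[:n_sig] *= sig_factor[None, :]
    for block in module_genes:
        f = np.exp(rng.normal(0.0, MODULE_FACTOR_SD, size=n_samples)
                   - MODULE_FACTOR_SD**2 / 2)
        idx = [genes.index(g) for g in block]
        mult[idx] *= f[None, :]

    mean = base[:, None] * mult * libsize[None, :]
    counts = _nb_draw(rng, mean, NB_DISPERSION)
    cm = CountMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        labels=labels,
    )

    effect: dict[str, dict[str, float]] = {}
    for gi, g in enumerate(genes):
        if gi < n_sig:
            effect[g] = {p.value: float(pop_mult[p][gi])
                         for p in ALL_POPULATIONS}
        else:
            effect[g] = {p.value: 1.0 for p in ALL_POPULATIONS}
    truth = GroundTruth(
        signature_genes=frozenset(sig_genes),
        module_map=module_map,
        effect=effect,
    )
    return cm, truth


def generate_protein(cm: CountMatrix, truth: GroundTruth,
                     detect_frac: float = 0.6,
                     seed: int = 0) -> tuple[ProteinTable, IDMap]:
    """Simulate a MaxQuant-style LFQ table coupled to the RNA data.

    A random ``detect_frac`` of genes get a protein row with accession
    ``"P" + gene``. Per-cell log2 intensity is
    ``20 + 1 * log2(RNA level in that sample) + N(0, 0.5)``, so protein
    abundance tracks the transcript with unit slope while proteins of
    unregulated genes stay null across populations; each cell drops out
    with probability logistic in minus intensity, concentrating
    missingness at low abundance. 2% of rows are flagged as contaminants.
    """
    if not 0 < detect_frac <= 1:
        raise ValueError("detect_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = cm.gene_ids
    n_detect = max(1, int(round(detect_frac * len(genes))))
    detected = sorted(rng.choice(len(genes), size=n_detect, replace=False))
    det_genes = [genes[i] for i in detected]

    counts = cm.values.clip(lower=1.0)
    samples = cm.sample_ids
    log2_int = np.empty((n_detect, len(samples)))
    for j, s in enumerate(samples):
        rna = np.log2(counts[s].iloc[detected].to_numpy())
        log2_int[:, j] = (PROTEIN_INTERCEPT + PROTEIN_SLOPE * rna
                          + rng.normal(0.0, PROTEIN_NOISE_SD, size=n_detect))
    p_missing = 1.0 / (1.0 + np.exp((log2_int - MISSING_MIDPOINT)
                                    / MISSING_SCALE))
    missing = rng.random(log2_int.shape) < p_missing
    linear = np.power(2.0, log2_int)
    linear[missing] = np.nan

    accs = [f"P{g}" for g in det_genes]
    inten = pd.DataFrame(linear, index=accs, columns=samples)
    contaminant = rng.random(n_detect) < CONTAMINANT_FRAC
    flags = pd.DataFrame(
        {
            "contaminant": contaminant,
            "reverse": np.zeros(n_detect, dtype=bool),
            "site_only": np.zeros(n_detect, dtype=bool),
        },
        index=accs,
    )
    pt = ProteinTable(
        intensities=inten,
        gene_names=pd.Series(det_genes, index=accs),
        flags=flags,
        labels=dict(cm.labels),
    )
    idmap = IDMap(pairs={a: g for a, g in zip(accs, det_genes)})
    return pt, idmap


def generate_annotation(truth: GroundTruth, all_genes: list[str],
                        n_terms: int = 50, n_enriched: int = 5,
                        seed: int = 0,
                        sig_member_frac: float = 0.6) -> tuple[
                            GeneSetCollection, GroundTruth]:
    """Simulate a flat GMT-style annotation with planted enriched terms.

    Planted terms draw ``sig_member_frac`` (>= 50%) of their members from
    the signature genes; background terms draw uniformly from all genes.
    Term sizes are uniform over [10, 200]. Returns the collection plus a
    copy of the ground truth with ``enriched_terms`` filled in.
    """
    if n_terms == 0:
        return GeneSetCollection([]), truth
    if sig_member_frac < 0.5:
        raise ValueError("planted terms must draw >= 50% from the signature")
    rng = np.random.default_rng(seed)
    sig = sorted(truth.signature_genes)
    terms: list[GeneSet] = []
    enriched: list[str] = []
    for t in range(n_terms):
        size = int(rng.integers(10, 201))
        tid = f"GO:{t:07d}"
        if t < n_enriched and sig:
            n_from_sig = min(len(sig), max(1, int(round(sig_member_frac
                                                        * size))))
            members = set(rng.choice(sig, size=n_from_sig, replace=False))
            pool = [g for g in all_genes if g not in members]
            extra = rng.choice(pool, size=size - n_from_sig, replace=False)
            members.update(extra)
            enriched.append(tid)
            name = f"planted effector process {t}"
        else:
            members = set(rng.choice(all_genes, size=size, replace=False))
            name = f"background process {t}"
        terms.append(GeneSet(tid, name, frozenset(members)))
    new_truth = GroundTruth(
        signature_genes=truth.signature_genes,
        module_map=dict(truth.module_map),
        effect=dict(truth.effect),
        enriched_terms=frozenset(enriched),
    )
    return GeneSetCollection(terms), new_truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist planted structure as a TSV (gene, is_signature, module)."""
    lines = ["gene\tis_signature\tmodule"]
    for g in sorted(truth.module_map):
        lines.append(
            f"{g}\t{int(g in truth.signature_genes)}\t{truth.module_map[g]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
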