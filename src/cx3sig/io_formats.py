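"""On-disk formats and core domain containers.

Readers validate strictly and report offending rows/columns; every
writer/reader pair is an exact inverse on valid data. Gene identifiers are
case-sensitive opaque strings matched exactly across files. All tables are
tab-separated UTF-8 with '.' decimal; missing protein intensities are
represented as NaN internally, never as 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# population labels
# ---------------------------------------------------------------------------

class PopulationLabel(str, enum.Enum):
    """The five sorted CD8+ T-cell populations.

    Naive CD62L-high CD45RA+ cells, and the four CD45RO+ memory populations
    defined by CX3CR1 and CD62L surface expression.
    """

    NAIVE = "NAIVE"
    CX3CR1P_CD62LHI = "CX3CR1P_CD62LHI"
    CX3CR1P_CD62LLO = "CX3CR1P_CD62LLO"
    CX3CR1N_CD62LHI = "CX3CR1N_CD62LHI"
    CX3CR1N_CD62LLO = "CX3CR1N_CD62LLO"


#: The two cytotoxic, CX3CR1-positive memory populations.
CX3CR1_POSITIVE = frozenset(
    {PopulationLabel.CX3CR1P_CD62LHI, PopulationLabel.CX3CR1P_CD62LLO}
)
#: The two CX3CR1-negative memory populations.
CX3CR1_NEGATIVE = frozenset(
    {PopulationLabel.CX3CR1N_CD62LHI, PopulationLabel.CX3CR1N_CD62LLO}
)

ALL_POPULATIONS: tuple[PopulationLabel, ...] = (
    PopulationLabel.CX3CR1P_CD62LHI,
    PopulationLabel.CX3CR1P_CD62LLO,
    PopulationLabel.CX3CR1N_CD62LHI,
    PopulationLabel.CX3CR1N_CD62LLO,
    PopulationLabel.NAIVE,
)


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


def labels_series(labels: dict[str, PopulationLabel], sample_ids) -> pd.Series:
    """Align a sample->population mapping with ``sample_ids``, validating
    completeness."""
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise FormatError(f"unlabeled samples: {missing[:10]}")
    return pd.Series({s: labels[s] for s in sample_ids}, name="population")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample read counts with sample-to-population labels.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    entries are non-negative integers. ``labels`` maps every sample id to a
    :class:`PopulationLabel`.
    """

    values: pd.DataFrame
    labels: dict[str, PopulationLabel]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("count matrix holds non-numeric entries")
        bad = np.argwhere(~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            g, s = bad[0]
            raise FormatError(
                f"count matrix entry for gene {self.values.index[g]!r}, sample "
                f"{self.values.columns[s]!r} is not a non-negative integer: "
                f"{arr[g, s]!r}"
            )
        labels_series(self.labels, self.values.columns)  # completeness

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def label_series(self) -> pd.Series:
        return labels_series(self.labels, self.values.columns)

    def samples_of(self, pop: PopulationLabel) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == pop]


def read_labels(path: str | Path) -> dict[str, PopulationLabel]:
    """Read a two-column TSV ``sample<TAB>population``."""
    labels: dict[str, PopulationLabel] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, pop = parts
        if sample in labels:
            raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
        try:
            labels[sample] = PopulationLabel(pop)
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: unknown population {pop!r}; admissible: "
                f"{[p.value for p in PopulationLabel]}"
            ) from exc
    return labels


def write_labels(labels: dict[str, PopulationLabel], path: str | Path) -> None:
    lines = [f"{s}\t{p.value}" for s, p in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_count_matrix(path: str | Path, labels_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample-label file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise FormatError(
                    f"{path}: non-numeric count in column {col!r}, "
                    f"gene {bad.index[0]!r}: {bad.iloc[0]!r}"
                )
    return CountMatrix(values=df, labels=read_labels(labels_path))


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       labels_path: str | Path | None = None) -> None:
    cm.values.astype(np.int64).to_csv(path, sep="\t", index_label="gene")
    if labels_path is not None:
        write_labels(cm.labels, labels_path)


# ---------------------------------------------------------------------------
# MaxQuant-style protein table
# ---------------------------------------------------------------------------

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "site_only": "Only identified by site",
}


@dataclass
class ProteinTable:
    """Label-free protein intensities (linear scale) with decoy/contaminant flags.

    ``intensities`` is protein x sample, NaN where the protein was not
    quantified in a sample. ``flags`` holds the three boolean filter columns.
    """

    intensities: pd.DataFrame
    gene_names: pd.Series
    flags: pd.DataFrame
    labels: dict[str, PopulationLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.intensities.index, "protein accessions")
        for key in FLAG_COLUMNS:
            if key not in self.flags.columns:
                raise FormatError(f"protein table flags lack {key!r}")
        arr = self.intensities.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] <= 0):
            bad = np.argwhere(np.isfinite(arr) & (arr <= 0))[0]
            raise FormatError(
                f"non-positive intensity for protein "
                f"{self.intensities.index[bad[0]]!r}, sample "
                f"{self.intensities.columns[bad[1]]!r}"
            )

    @property
    def accessions(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)


def _parse_flag(col: pd.Series, name: str, path) -> pd.Series:
    filled = col.fillna("")
    ok = filled.isin(["+", ""])
    if not ok.all():
        bad = filled[~ok]
        raise FormatError(
            f"{path}: malformed value {bad.iloc[0]!r} in flag column {name!r} "
            f"(row {bad.index[0]!r}); expected '+' or empty"
        )
    return filled == "+"


def read_protein_table(path: str | Path,
                       labels_path: str | Path | None = None) -> ProteinTable:
    """Read a MaxQuant ``proteinGroups``-style TSV.

    Intensity columns are ``LFQ intensity <sample>``; zero intensities mean
    "not quantified" and become NaN. Flag columns hold '+' or empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    acc_col = None
    for cand in ("Majority protein IDs", "Protein IDs", "accession"):
        if cand in df.columns:
            acc_col = cand
            break
    if acc_col is None:
        raise FormatError(f"{path}: no protein accession column found")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(
            f"{path}: no 'LFQ intensity <sample>' columns found"
        )
    raw = df[lfq_cols]
    inten = raw.apply(pd.to_numeric, errors="coerce")
    malformed = inten.isna() & raw.notna() & (raw != "")
    if malformed.to_numpy().any():
        i, j = np.argwhere(malformed.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric LFQ intensity {raw.iloc[i, j]!r} in column "
            f"{lfq_cols[j]!r}, row {i + 2}"
        )
    inten = inten.fillna(0.0)
    inten = inten.mask(inten == 0.0)  # MaxQuant: 0 == not quantified
    inten.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    inten.index = pd.Index(df[acc_col].astype(str).to_numpy())

    flags = pd.DataFrame(index=inten.index)
    for key, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[key] = _parse_flag(df[col].set_axis(inten.index), col, path).to_numpy()
        else:
            flags[key] = False

    genes = (
        df["Gene names"].fillna("").astype(str).set_axis(inten.index)
        if "Gene names" in df.columns
        else pd.Series("", index=inten.index)
    )
    labels = read_labels(labels_path) if labels_path is not None else {}
    return ProteinTable(intensities=inten, gene_names=genes, flags=flags,
                        labels=labels)


def write_protein_table(pt: ProteinTable, path: str | Path) -> None:
    """Write a ProteinTable back to the MaxQuant dialect (NaN -> 0)."""
    out = pd.DataFrame({"Majority protein IDs": pt.intensities.index,
                        "Gene names": pt.gene_names.to_numpy()})
    for s in pt.intensities.columns:
        out[LFQ_PREFIX + s] = pt.intensities[s].fillna(0.0).to_numpy()
    for key, col in FLAG_COLUMNS.items():
        out[col] = np.where(pt.flags[key].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and accession->symbol map
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    terms: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([t.term_id for t in self.terms], "term ids")
        for t in self.terms:
            if not t.genes:
                raise FormatError(f"gene set {t.term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def get(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


def read_gmt(path: str | Path) -> GeneSetCollection:
    terms: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs id, description and >=1 gene"
            )
        term_id, name, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
        terms.append(GeneSet(term_id, name, frozenset(genes)))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.name, *sorted(t.genes)]) for t in collection
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class IDMap:
    """Protein accession -> gene symbol (many-to-one allowed)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        for acc, sym in self.pairs.items():
            if not sym:
                raise FormatError(f"empty gene symbol for accession {acc!r}")

    def get(self, accession: str) -> str | None:
        return self.pairs.get(accession)

    def __len__(self) -> int:
        return len(self.pairs)


def read_id_map(path: str | Path) -> IDMap:
    pairs: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected accession<TAB>symbol")
        acc, sym = parts
        if acc in pairs:
            raise FormatError(f"{path}:{lineno}: duplicate accession {acc!r}")
        if not sym:
            raise FormatError(f"{path}:{lineno}: empty symbol for {acc!r}")
        pairs[acc] = sym
    return IDMap(pairs)


def write_id_map(idmap: IDMap, path: str | Path) -> None:
    lines = [f"{a}\t{s}" for a, s in idmap.pairs.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# signature and network tables (thin wrappers; see signature/goea modules)
# ---------------------------------------------------------------------------

def write_signature(sig, path: str | Path) -> None:
    """Write a SignatureSet as TSV (gene, provenance, stage, omics)."""
    from .signature import SignatureSet  # local import avoids a cycle

    assert isinstance(sig, SignatureSet)
    rows = ["gene\tprovenance\tstage\tomics"]
    for g in sig.genes:
        prov = ",".join(sorted(sig.provenance[g]))
        rows.append(f"{g}\t{prov}\t{sig.stage}\t{sig.omics}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_signature(path: str | Path):
    from .signature import SignatureSet

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["gene", "provenance", "stage", "omics"]:
        raise FormatError(f"{path}: missing signature header")
    genes: list[str] = []
    prov: dict[str, frozenset[str]] = {}
    stage = "pre"
    omics = "rna"
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        g, p, stage, omics = parts
        genes.append(g)
        prov[g] = frozenset(x for x in p.split(",") if x)
    return SignatureSet(genes=genes, provenance=prov, stage=stage, omics=omics)


def write_network(net, node_path: str | Path, edge_path: str | Path) -> None:
    """Write an enrichment network as node and edge TSVs."""
    node_rows = ["term_id\tname\tq\tk"]
    for term_id, data in sorted(net.nodes(data=True)):
        node_rows.append(
            f"{term_id}\t{data.get('name', '')}\t{data.get('q', '')}\t{data.get('k', '')}"
        )
    Path(node_path).write_text("\n".join(node_rows) + "\n")
    edge_rows = ["term_a\tterm_b\tjaccard"]
    for a, b, data in sorted(net.edges(data=True)):
        edge_rows.append(f"{a}\t{b}\t{data['jaccard']:.6g}")
    Path(edge_path).write_text("\n".join(edge_rows) + "\n")
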