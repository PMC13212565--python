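"""Readers, writers and the shared tabular data model.

Every downstream module consumes the types defined here. Coordinates are
1-based inclusive (GFF3 convention); sequences are uppercase IUPAC DNA.
All tables are headered TSV; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HABITATS = ("soil", "sediment", "freshwater", "other")
PRODUCT_CLASSES = ("sigma_factor", "other")

#: accepted nucleotide alphabet: A/C/G/T, N and the IUPAC ambiguity codes
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

_KO_RE = re.compile(r"^K\d{5}$")

GENE_TABLE_COLUMNS = (
    "genome_id", "contig_id", "gene_id", "start", "end", "strand", "product_class",
)
METADATA_COLUMNS = (
    "genome_id", "completeness_pct", "contamination_pct", "habitat", "lineage",
)
ANNOTATION_COLUMNS = ("genome_id", "gene_id", "ko_id")
ABUNDANCE_COLUMNS = ("sample_id", "habitat", "taxon", "rel_abundance_pct")


class FormatError(ValueError):
    """Raised when an input file or record violates the data model."""


@dataclass(frozen=True)
class GeneCoord:
    """One gene on a contig. ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product_class: str = "other"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"start={self.start}, end={self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.product_class not in PRODUCT_CLASSES:
            raise FormatError(
                f"gene {self.gene_id!r}: unknown product_class {self.product_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One assembly: contigs, gene coordinates, quality and habitat metadata."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneCoord] = field(default_factory=list)
    completeness_pct: float = 100.0
    contamination_pct: float = 0.0
    habitat: str = "other"
    lineage: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.completeness_pct <= 100):
            raise FormatError(
                f"{self.genome_id}: completeness_pct must be in (0, 100], "
                f"got {self.completeness_pct}"
            )
        if not (0 <= self.contamination_pct < 100):
            raise FormatError(
                f"{self.genome_id}: contamination_pct must be in [0, 100), "
                f"got {self.contamination_pct}"
            )
        if self.habitat not in HABITATS:
            raise FormatError(
                f"{self.genome_id}: habitat must be one of {HABITATS}, "
                f"got {self.habitat!r}"
            )
        for contig_id, seq in self.contigs.items():
            bad = sorted(set(seq) - DNA_ALPHABET)
            if bad:
                raise FormatError(
                    f"{self.genome_id}/{contig_id}: non-DNA characters {bad}"
                )
        for gene in self.genes:
            if gene.contig_id not in self.contigs:
                raise FormatError(
                    f"gene {gene.gene_id!r} references missing contig "
                    f"{gene.contig_id!r} in genome {self.genome_id}"
                )
            clen = len(self.contigs[gene.contig_id])
            if gene.end > clen:
                raise FormatError(
                    f"gene {gene.gene_id!r} end={gene.end} exceeds contig "
                    f"{gene.contig_id!r} length {clen}"
                )

    @property
    def assembled_length_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def genes_by_contig(self) -> dict[str, list[GeneCoord]]:
        out: dict[str, list[GeneCoord]] = {c: [] for c in self.contigs}
        for g in self.genes:
            out[g.contig_id].append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end))
        return out


@dataclass
class AnnotationTable:
    """Per-genome functional annotations: (gene_id, KO id) pairs.

    A gene carries zero or one KO; duplicated KO ids across genes are the
    substrate of the functional-redundancy ratio.
    """

    genome_id: str
    annotations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene_id, ko in self.annotations:
            if not _KO_RE.match(ko):
                raise FormatError(
                    f"{self.genome_id}/{gene_id}: malformed KO id {ko!r} "
                    "(expected K followed by 5 digits)"
                )

    def kos(self) -> list[str]:
        """All KO assignments, with multiplicity."""
        return [ko for _, ko in self.annotations]

    def ko_set(self) -> frozenset[str]:
        return frozenset(ko for _, ko in self.annotations)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Tabular readers

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, GENE_TABLE_COLUMNS)
    df = df.astype({"start": int, "end": int})
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, METADATA_COLUMNS)
    df = df.astype({"completeness_pct": float, "contamination_pct": float})
    return df


def read_annotation_tables(path: str | Path) -> dict[str, AnnotationTable]:
    """Read an annotation TSV into one :class:`AnnotationTable` per genome."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    out: dict[str, AnnotationTable] = {}
    for genome_id, sub in df.groupby("genome_id", sort=True):
        out[str(genome_id)] = AnnotationTable(
            genome_id=str(genome_id),
            annotations=list(zip(sub["gene_id"], sub["ko_id"])),
        )
    return out


def write_annotation_tables(
    tables: Iterable[AnnotationTable], path: str | Path
) -> None:
    rows = [
        (t.genome_id, gene_id, ko)
        for t in tables
        for gene_id, ko in t.annotations
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ABUNDANCE_COLUMNS)
    df = df.astype({"rel_abundance_pct": float})
    validate_abundance_table(df)
    return df


def validate_abundance_table(df: pd.DataFrame) -> None:
    vals = df["rel_abundance_pct"]
    if (vals < 0).any() or (vals > 100).any():
        bad = df.loc[(vals < 0) | (vals > 100), "sample_id"].tolist()[:5]
        raise FormatError(f"abundances outside [0, 100] in samples {bad}")
    sums = df.groupby("sample_id")["rel_abundance_pct"].sum()
    over = sums[sums > 100 + 1e-6]
    if len(over):
        raise FormatError(
            f"per-sample abundance sums exceed 100%: {over.index.tolist()[:5]}"
        )
    bad_hab = sorted(set(df["habitat"]) - set(HABITATS))
    if bad_hab:
        raise FormatError(f"unknown habitat label(s) {bad_hab}")


# ---------------------------------------------------------------------------
# Genome bundle

def read_genome_bundle(
    fasta_path: str | Path,
    gene_table_path: str | Path,
    metadata_path: str | Path,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Assemble a validated :class:`GenomeRecord` from its three files.

    ``genome_id`` selects the metadata row (and gene-table rows); it may be
    omitted when the metadata file describes exactly one genome. An empty
    gene table yields a record whose whole assembly is intergenic.
    """
    contigs = read_fasta(fasta_path)
    meta = read_metadata(metadata_path)
    if genome_id is None:
        if len(meta) != 1:
            raise FormatError(
                f"{metadata_path}: {len(meta)} metadata rows; pass genome_id"
            )
        genome_id = str(meta["genome_id"].iloc[0])
    row = meta[meta["genome_id"] == genome_id]
    if len(row) != 1:
        raise FormatError(
            f"{metadata_path}: expected exactly one row for {genome_id!r}, "
            f"found {len(row)}"
        )
    row = row.iloc[0]

    genes_df = read_gene_table(gene_table_path)
    genes_df = genes_df[genes_df["genome_id"] == genome_id]
    genes = [
        GeneCoord(
            gene_id=r.gene_id,
            contig_id=r.contig_id,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            product_class=(
                r.product_class if isinstance(r.product_class, str) else "other"
            ),
        )
        for r in genes_df.itertuples()
    ]
    return GenomeRecord(
        genome_id=genome_id,
        contigs=contigs,
        genes=genes,
        completeness_pct=float(row["completeness_pct"]),
        contamination_pct=float(row["contamination_pct"]),
        habitat=str(row["habitat"]),
        lineage=str(row["lineage"]),
    )


def write_gene_table(records: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = [
        (r.genome_id, g.contig_id, g.gene_id, g.start, g.end, g.strand,
         g.product_class)
        for r in records
        for g in r.genes
    ]
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_metadata(records: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = [
        (r.genome_id, r.completeness_pct, r.contamination_pct, r.habitat,
         r.lineage)
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_gff3_genes(path: str | Path, genome_id: str = "") -> list[GeneCoord]:
    """Thin GFF3 import: columns 1 (contig), 4/5 (start/end), 7 (strand) and
    the ``ID`` attribute. Feature types other than gene/CDS are skipped.
    """
    genes: list[GeneCoord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID", f"{contig}_{lineno}")
            product_class = attr_map.get("product_class", "other")
            genes.append(
                GeneCoord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product_class=product_class,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Trees

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; all edges must carry non-negative lengths.

    A missing root edge length is treated as 0 (the two Newick spellings
    ``(...);`` and ``(...):0.0;`` denote the same tree).
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError(f"{path}: unlabeled tip in tree")
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if node.parent_node is None:
            if length is None:
                node.edge.length = 0.0
            elif length < 0:
                raise FormatError(f"{path}: negative root edge length {length}")
            continue
        if length is None:
            raise FormatError(
                f"{path}: edge above {_node_label(node)!r} has no branch length"
            )
        if length < 0:
            raise FormatError(
                f"{path}: negative branch length {length} above "
                f"{_node_label(node)!r}"
            )
    return tree


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or "<internal>"


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Matrices

def write_matrix(
    matrix,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    path: str | Path,
) -> None:
    """Write a rectangular numeric matrix as headered TSV.

    Row labels occupy column 1; floats are rendered at 6 significant digits.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(len(row_labels), len(col_labels))
    if arr.ndim != 2:
        raise FormatError(f"matrix must be 2-D, got ndim={arr.ndim}")
    if arr.shape != (len(row_labels), len(col_labels)):
        raise FormatError(
            f"matrix shape {arr.shape} does not match "
            f"{len(row_labels)} row / {len(col_labels)} column labels"
        )
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *map(str, col_labels)]) + "\n")
        for label, row in zip(row_labels, arr):
            cells = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{label}\t{cells}\n" if len(row) else f"{label}\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [
        str(c) for c in df.columns
    ]
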