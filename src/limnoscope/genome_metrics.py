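"""Genome-architecture statistics.

Quality-corrected genome size, GC content (overall / genic / intergenic),
coding density, intergenic spacer lengths and normalized sigma-factor
counts — the per-genome panel behind family- and habitat-level contrasts.

Overlapping gene intervals are merged once before any density or spacer
computation, so coding density is bounded by 1 and spacers are maximal
non-genic runs. Contig-terminal intergenic flanks are artifacts of where an
assembly happens to start and end, so they are reported separately and
excluded from spacer medians. GC is strand-symmetric: no gene is
reverse-complemented for any GC-type metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeRecord


@dataclass
class GenomeMetrics:
    genome_id: str
    assembled_length_bp: int
    corrected_size_bp: float
    gc_overall_pct: float
    gc_genic_pct: float
    gc_intergenic_pct: float
    coding_density_fraction: float
    spacer_lengths_bp: list[int]
    sigma_per_1000_genes: float
    n_genes: int

    @property
    def median_spacer_bp(self) -> float:
        if not self.spacer_lengths_bp:
            return math.nan
        return float(np.median(self.spacer_lengths_bp))


def corrected_genome_size(
    length_bp: float, completeness_pct: float, contamination_pct: float
) -> float:
    """Quality-corrected genome size.

    The assembled length is divided by the estimated completeness and the
    result multiplied by (100 - contamination) / 100: missing content is
    imputed, contaminating content removed.
    """
    if completeness_pct <= 0:
        raise ValueError(f"completeness must be positive, got {completeness_pct}")
    if completeness_pct > 100 or not (0 <= contamination_pct < 100):
        raise ValueError(
            f"completeness {completeness_pct} / contamination "
            f"{contamination_pct} outside valid percent ranges"
        )
    return length_bp * (100.0 / completeness_pct) * (
        (100.0 - contamination_pct) / 100.0
    )


def gc_content(seq: str) -> float:
    """GC percent over unambiguous bases; N and IUPAC ambiguity codes are
    excluded from numerator and denominator. NaN when nothing is countable."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    gc = sum(seq.count(b) for b in "GCgc")
    at = sum(seq.count(b) for b in "ATat")
    if gc + at == 0:
        return math.nan
    return 100.0 * gc / (gc + at)


def merged_intervals(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent-by-overlap 1-based inclusive intervals."""
    if not intervals:
        return []
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            # overlapping or book-ended: one genic run either way
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _contig_partition(
    seq: str, genes: list
) -> tuple[list[tuple[int, int]], list[str], list[str], list[int], list[int]]:
    """Per-contig merged genic intervals, genic/intergenic subsequences and
    internal-spacer / terminal-flank lengths."""
    merged = merged_intervals([(g.start, g.end) for g in genes])
    genic = [seq[s - 1:e] for s, e in merged]
    intergenic: list[str] = []
    internal: list[int] = []
    terminal: list[int] = []
    if not merged:
        if seq:
            intergenic.append(seq)
            terminal.append(len(seq))
        return merged, genic, intergenic, internal, terminal
    lead = merged[0][0] - 1
    if lead > 0:
        intergenic.append(seq[:lead])
        terminal.append(lead)
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        gap = s2 - e1 - 1
        if gap > 0:
            intergenic.append(seq[e1:s2 - 1])
            internal.append(gap)
    trail = len(seq) - merged[-1][1]
    if trail > 0:
        intergenic.append(seq[merged[-1][1]:])
        terminal.append(trail)
    return merged, genic, intergenic, internal, terminal


def partition_gc(
    genome: GenomeRecord,
) -> tuple[float, float, int, int]:
    """(gc_genic_pct, gc_intergenic_pct, genic_bp, intergenic_bp).

    Genic bases are the union of (merged) gene intervals; intergenic bases
    are the complement within each contig. GC is computed over the
    concatenation of each class; an empty class yields NaN.
    """
    genic_parts: list[str] = []
    inter_parts: list[str] = []
    for contig_id, genes in genome.genes_by_contig().items():
        seq = genome.contigs[contig_id]
        _, genic, intergenic, _, _ = _contig_partition(seq, genes)
        genic_parts += genic
        inter_parts += intergenic
    genic_seq = "".join(genic_parts)
    inter_seq = "".join(inter_parts)
    gc_genic = gc_content(genic_seq) if genic_seq else math.nan
    gc_inter = gc_content(inter_seq) if inter_seq else math.nan
    return gc_genic, gc_inter, len(genic_seq), len(inter_seq)


def coding_density(genome: GenomeRecord) -> float:
    """Merged genic bp over assembled bp (0 for a geneless assembly)."""
    total = genome.assembled_length_bp
    if total == 0:
        return 0.0
    genic = 0
    for contig_id, genes in genome.genes_by_contig().items():
        genic += sum(
            e - s + 1 for s, e in merged_intervals([(g.start, g.end) for g in genes])
        )
    return genic / total


def spacer_lengths(genome: GenomeRecord) -> list[int]:
    """Lengths of maximal intergenic runs strictly between merged genes on
    the same contig (contig-terminal flanks excluded; see
    :func:`terminal_flank_lengths`)."""
    out: list[int] = []
    for contig_id, genes in genome.genes_by_contig().items():
        _, _, _, internal, _ = _contig_partition(genome.contigs[contig_id], genes)
        out += internal
    return out


def terminal_flank_lengths(genome: GenomeRecord) -> list[int]:
    """Intergenic runs touching a contig end (assembly artifacts, not true
    spacers)."""
    out: list[int] = []
    for contig_id, genes in genome.genes_by_contig().items():
        _, _, _, _, terminal = _contig_partition(genome.contigs[contig_id], genes)
        out += terminal
    return out


def sigma_rate(genome: GenomeRecord) -> float:
    """Sigma-factor genes per 1000 genes; NaN for a geneless genome."""
    n = len(genome.genes)
    if n == 0:
        return math.nan
    n_sigma = sum(1 for g in genome.genes if g.product_class == "sigma_factor")
    return 1000.0 * n_sigma / n


def genome_metrics(genome: GenomeRecord) -> GenomeMetrics:
    gc_genic, gc_inter, genic_bp, inter_bp = partition_gc(genome)
    all_seq = "".join(genome.contigs.values())
    return GenomeMetrics(
        genome_id=genome.genome_id,
        assembled_length_bp=genome.assembled_length_bp,
        corrected_size_bp=corrected_genome_size(
            genome.assembled_length_bp,
            genome.completeness_pct,
            genome.contamination_pct,
        ),
        gc_overall_pct=gc_content(all_seq) if all_seq else math.nan,
        gc_genic_pct=gc_genic,
        gc_intergenic_pct=gc_inter,
        coding_density_fraction=coding_density(genome),
        spacer_lengths_bp=spacer_lengths(genome),
        sigma_per_1000_genes=sigma_rate(genome),
        n_genes=len(genome.genes),
    )


def metrics_table(genomes: list[GenomeRecord]) -> pd.DataFrame:
    """One row per genome; the genome-architecture panel."""
    rows = []
    for g in genomes:
        m = genome_metrics(g)
        rows.append(
            {
                "genome_id": m.genome_id,
                "lineage": g.lineage,
                "habitat": g.habitat,
                "assembled_length_bp": m.assembled_length_bp,
                "corrected_size_bp": m.corrected_size_bp,
                "gc_overall_pct": m.gc_overall_pct,
                "gc_genic_pct": m.gc_genic_pct,
                "gc_intergenic_pct": m.gc_intergenic_pct,
                "coding_density_fraction": m.coding_density_fraction,
                "median_spacer_bp": m.median_spacer_bp,
                "n_spacers": len(m.spacer_lengths_bp),
                "sigma_per_1000_genes": m.sigma_per_1000_genes,
                "n_genes": m.n_genes,
            }
        )
    return pd.DataFrame(rows)
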