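"""Codon-frequency profiling, amino-acid composition and GC by codon
position, plus the synonymous-family trend summary ("funnel" dynamics).

CDS are read 5'->3' on the coding strand (minus-strand genes must be
reverse-complemented upstream); counting walks each CDS in frames of three.
Trailing 1-2 nt remainders and triplets containing non-ACGT characters are
dropped, not imputed, and the dropped counts are kept for auditability.
Stop codons are counted in the 64-codon table but excluded from the
synonymous-family trend, which concerns amino-acid-preserving replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._genetic_code import (
    AA_INDEX,
    AA_ORDER,
    AA_TO_CODONS,
    CODON_INDEX,
    CODONS,
    DEGENERATE_AAS,
    GC3_CODONS,
    STOP_CODONS,
)

_ACGT = frozenset("ACGT")


@dataclass
class CodonProfile:
    """Per-genome normalized frequencies over all 64 codons."""

    genome_id: str
    freq: np.ndarray                  # 64-vector, sums to 1 when any codon kept
    total_codons: int
    gc_by_position: tuple[float, float, float]   # GC1, GC2, GC3 in percent
    n_dropped_ambiguous: int = 0
    n_dropped_remainder_nt: int = 0

    def counts(self) -> np.ndarray:
        return np.rint(self.freq * self.total_codons).astype(int)


@dataclass
class AAProfile:
    """Amino-acid composition in percent over the 20 standard residues."""

    sequence_id: str
    pct: np.ndarray                   # 20-vector, sums to 100
    n_residues: int


def strip_terminal_stop(cds: str) -> str:
    """Drop the final triplet when it is a stop codon on the coding strand."""
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def _iter_codons(cds_list: Iterable[str]):
    """Yield (kept codon | None-for-ambiguous) plus remainder bookkeeping."""
    for seq in cds_list:
        seq = seq.upper()
        n_full = len(seq) // 3
        for i in range(n_full):
            yield seq[3 * i:3 * i + 3]
        if len(seq) % 3:
            yield ("__REMAINDER__", len(seq) % 3)


def codon_frequencies(
    cds_list: Sequence[str], genome_id: str = ""
) -> CodonProfile:
    """Pool frame-0 triplet counts across all CDS of a genome.

    Empty input yields a zero profile with ``total_codons == 0``.
    """
    counts = np.zeros(64, dtype=np.int64)
    pos_gc = np.zeros(3)
    pos_n = np.zeros(3)
    n_ambig = 0
    n_rem = 0
    for item in _iter_codons(cds_list):
        if isinstance(item, tuple):
            n_rem += item[1]
            continue
        codon = item
        idx = CODON_INDEX.get(codon)
        if idx is None:  # contains non-ACGT
            n_ambig += 1
            # unambiguous positions of a dropped triplet still carry no
            # weight: the whole triplet is dropped from both tallies
            continue
        counts[idx] += 1
        for p, base in enumerate(codon):
            pos_n[p] += 1
            if base in "GC":
                pos_gc[p] += 1
    total = int(counts.sum())
    freq = counts / total if total else np.zeros(64)
    gc_pos = tuple(
        100.0 * g / n if n else math.nan for g, n in zip(pos_gc, pos_n)
    )
    return CodonProfile(
        genome_id=genome_id,
        freq=freq,
        total_codons=total,
        gc_by_position=gc_pos,  # type: ignore[arg-type]
        n_dropped_ambiguous=n_ambig,
        n_dropped_remainder_nt=n_rem,
    )


def gc_by_codon_position(
    cds_list: Sequence[str],
) -> tuple[float, float, float]:
    """GC percent at codon positions 1-3 across kept codons."""
    return codon_frequencies(cds_list).gc_by_position


def aa_composition(
    proteins: Sequence[str], sequence_id: str = ""
) -> AAProfile:
    """Pooled (residue-count-weighted) amino-acid composition of a protein
    set; X/B/Z/U/* and other nonstandard symbols are excluded from numerator
    and denominator. An empty input raises ``ValueError`` (missing profile).
    """
    counts = np.zeros(len(AA_ORDER), dtype=np.int64)
    for seq in proteins:
        for aa in seq.upper():
            idx = AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
    total = int(counts.sum())
    if total == 0:
        raise ValueError(
            f"{sequence_id or 'input'}: no standard residues to profile"
        )
    return AAProfile(
        sequence_id=sequence_id, pct=100.0 * counts / total, n_residues=total
    )


def aa_composition_per_sequence(
    proteins: dict[str, str]
) -> dict[str, AAProfile]:
    return {
        name: aa_composition([seq], sequence_id=name)
        for name, seq in proteins.items()
    }


def gc_ending_share(profile: CodonProfile, aa: str) -> float:
    """Within-family share of G/C-ending codons for one amino acid; NaN when
    the family is unobserved in the profile."""
    codons = AA_TO_CODONS[aa]
    fam = sum(profile.freq[CODON_INDEX[c]] for c in codons)
    if fam == 0:
        return math.nan
    gc = sum(
        profile.freq[CODON_INDEX[c]] for c in codons if c in GC3_CODONS
    )
    return gc / fam


def synonymous_family_trend(
    profiles_by_group: Sequence[tuple[str, Sequence[CodonProfile]]],
) -> pd.DataFrame:
    """Per-family GC-ending-share trend across ordered lineage groups.

    For each of the 18 synonymous families with third-position degeneracy,
    reports the per-group mean within-family share of GC-ending codons, the
    Kendall trend sign across the group order, and whether the share
    declines monotonically. The summary fraction of declining families (the
    "funnel" share) is stored in ``df.attrs["fraction_decreasing"]``.
    """
    if len(profiles_by_group) < 2:
        raise ValueError("need at least 2 ordered groups")
    group_names = [name for name, _ in profiles_by_group]
    rows = []
    n_decreasing = 0
    for aa in DEGENERATE_AAS:
        means = []
        for _, profiles in profiles_by_group:
            shares = [gc_ending_share(p, aa) for p in profiles]
            shares = [s for s in shares if not math.isnan(s)]
            means.append(float(np.mean(shares)) if shares else math.nan)
        arr = np.asarray(means)
        if np.isnan(arr).any() or np.allclose(arr, arr[0]):
            sign = 0
        else:
            tau = stats.kendalltau(np.arange(len(arr)), arr).statistic
            sign = int(np.sign(tau)) if not math.isnan(tau) else 0
        monotone_dec = bool(
            not np.isnan(arr).any() and np.all(np.diff(arr) < 0)
        )
        n_decreasing += monotone_dec
        rows.append(
            {
                "family": aa,
                **{f"mean_gc_share[{g}]": m for g, m in zip(group_names, means)},
                "trend_sign": sign,
                "monotone_decreasing": monotone_dec,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["fraction_decreasing"] = n_decreasing / len(DEGENERATE_AAS)
    df.attrs["n_decreasing"] = n_decreasing
    df.attrs["n_families"] = len(DEGENERATE_AAS)
    return df


def codon_matrix(profiles: Sequence[CodonProfile]) -> pd.DataFrame:
    """64 rows (codons) x one column per genome, frequencies."""
    return pd.DataFrame(
        {p.genome_id: p.freq for p in profiles}, index=list(CODONS)
    )


def aa_matrix(profiles: Sequence[AAProfile]) -> pd.DataFrame:
    """20 rows (residues) x one column per proteome, percentages."""
    return pd.DataFrame(
        {p.sequence_id: p.pct for p in profiles}, index=list(AA_ORDER)
    )
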