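"""KO-based functional profiles: habitat pooling, Jaccard similarity and
the functional redundancy ratio (FRR).

Pooling is presence/absence (set union over member genomes), not abundance
weighted. FRR = 1 - unique/total KO annotations per genome: 0 means every
annotated function is encoded once; values near 1 mean heavy duplication.
Genes without a KO are outside the FRR denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .core_io import AnnotationTable


@dataclass(frozen=True)
class HabitatPool:
    """Union of KO ids across all genomes sharing one label."""

    habitat: str
    kos: frozenset[str]
    n_genomes: int


def pool_by_group(
    tables: Iterable[AnnotationTable],
    labels: Mapping[str, str],
    expected_labels: Sequence[str] | None = None,
) -> list[HabitatPool]:
    """Pool each genome's KO set into its label's composite gene set.

    Every genome must be labeled; ``expected_labels`` may add labels that
    should appear even if no genome carries them (an empty pool is emitted
    with a warning).
    """
    pools: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for label in expected_labels or ():
        pools.setdefault(label, set())
        counts.setdefault(label, 0)
    for table in tables:
        if table.genome_id not in labels:
            raise ValueError(f"genome {table.genome_id!r} has no label")
        label = labels[table.genome_id]
        pools.setdefault(label, set()).update(table.ko_set())
        counts[label] = counts.get(label, 0) + 1
    out = []
    for label in sorted(pools):
        if counts.get(label, 0) == 0:
            warnings.warn(f"label {label!r} has no genomes; empty pool")
        out.append(
            HabitatPool(
                habitat=label, kos=frozenset(pools[label]),
                n_genomes=counts.get(label, 0),
            )
        )
    return out


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a n b| / |a u b|; two empty sets are defined as 0 (flagged)."""
    a, b = frozenset(a), frozenset(b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(pools: Sequence[HabitatPool]) -> pd.DataFrame:
    """Symmetric similarity matrix over habitat pools, unit diagonal for
    non-empty pools."""
    labels = [p.habitat for p in pools]
    mat = pd.DataFrame(
        np.eye(len(pools)), index=labels, columns=labels, dtype=float
    )
    for p in pools:
        if not p.kos:
            mat.loc[p.habitat, p.habitat] = 0.0
    for p, q in combinations(pools, 2):
        val = jaccard(p.kos, q.kos)
        mat.loc[p.habitat, q.habitat] = val
        mat.loc[q.habitat, p.habitat] = val
    return mat


def frr(table: AnnotationTable) -> float:
    """Functional redundancy ratio: 1 - distinct/total KO annotations."""
    total = len(table.annotations)
    if total == 0:
        warnings.warn(f"{table.genome_id}: no KO annotations; FRR undefined")
        return math.nan
    return 1.0 - len(table.ko_set()) / total


def frr_table(
    tables: Iterable[AnnotationTable],
    lineages: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rows = [
        {
            "genome_id": t.genome_id,
            "lineage": (lineages or {}).get(t.genome_id, ""),
            "n_annotations": len(t.annotations),
            "n_distinct_kos": len(t.ko_set()),
            "frr": frr(t) if t.annotations else math.nan,
        }
        for t in tables
    ]
    return pd.DataFrame(rows)
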