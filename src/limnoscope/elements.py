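"""Elemental stoichiometry of predicted proteomes.

Carbon and nitrogen atoms per residue use the side-chain-inclusive
molecular formulas of the free amino acids. Peptide-bond condensation
removes only water (H and O), so carbon and nitrogen per residue are
unaffected by whether the free-acid or residue formula is used. The full
CHNOS table is kept; the analyses surface C and N.

The proteome mean is the unweighted arithmetic mean of per-protein values
(each protein's atoms-per-residue is computed first, then proteins are
averaged); a residue-weighted variant is also computed for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: free-amino-acid molecular formulas: one-letter code -> atom counts
RESIDUE_ATOMS: dict[str, dict[str, int]] = {
    "A": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 0},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2, "S": 0},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3, "S": 0},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4, "S": 0},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3, "S": 0},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4, "S": 0},
    "G": {"C": 2, "H": 5, "N": 1, "O": 2, "S": 0},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2, "S": 0},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2, "S": 0},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2, "S": 0},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2, "S": 0},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2, "S": 0},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2, "S": 0},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3, "S": 0},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3, "S": 0},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 0},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2, "S": 0},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3, "S": 0},
}

_C = {aa: v["C"] for aa, v in RESIDUE_ATOMS.items()}
_N = {aa: v["N"] for aa, v in RESIDUE_ATOMS.items()}


@dataclass
class ElementalProfile:
    """Mean carbon and nitrogen atoms per residue for one proteome."""

    genome_id: str
    mean_c_per_aa: float
    mean_n_per_aa: float
    n_proteins: int
    #: residue-weighted alternative (total atoms / total residues)
    weighted_c_per_aa: float = math.nan
    weighted_n_per_aa: float = math.nan


def protein_cn(protein: str) -> tuple[float, float]:
    """(carbon, nitrogen) atoms per counted residue of one protein.

    Nonstandard symbols (X/B/Z/U/*, gaps) are excluded from both the atom
    sums and the length; a protein with no countable residue returns NaNs.
    """
    c = n = length = 0
    for aa in protein.upper():
        if aa in _C:
            c += _C[aa]
            n += _N[aa]
            length += 1
    if length == 0:
        return math.nan, math.nan
    return c / length, n / length


def proteome_cn(
    proteins: Sequence[str] | Mapping[str, str], genome_id: str = ""
) -> ElementalProfile:
    """Unweighted mean of per-protein C and N per residue (primary), plus
    the residue-weighted alternative."""
    seqs = list(proteins.values()) if isinstance(proteins, Mapping) else list(proteins)
    per_protein = [protein_cn(s) for s in seqs]
    per_protein = [(c, n) for c, n in per_protein if not math.isnan(c)]
    if not per_protein:
        raise ValueError(f"{genome_id or 'proteome'}: no valid proteins")
    cs, ns = zip(*per_protein)

    tot_c = tot_n = tot_len = 0
    for s in seqs:
        for aa in s.upper():
            if aa in _C:
                tot_c += _C[aa]
                tot_n += _N[aa]
                tot_len += 1
    return ElementalProfile(
        genome_id=genome_id,
        mean_c_per_aa=float(np.mean(cs)),
        mean_n_per_aa=float(np.mean(ns)),
        n_proteins=len(per_protein),
        weighted_c_per_aa=tot_c / tot_len,
        weighted_n_per_aa=tot_n / tot_len,
    )


def expected_cn_from_aa_usage(aa_usage: np.ndarray) -> tuple[float, float]:
    """Expected (C, N) per residue for i.i.d. residues drawn from a 20-vector
    of amino-acid probabilities (alphabetical one-letter order)."""
    from ._genetic_code import AA_ORDER

    aa_usage = np.asarray(aa_usage, float)
    c = sum(p * _C[aa] for aa, p in zip(AA_ORDER, aa_usage))
    n = sum(p * _N[aa] for aa, p in zip(AA_ORDER, aa_usage))
    return float(c), float(n)


def cn_relationship(
    profiles: Sequence[ElementalProfile],
    group_labels: Sequence[str] | None = None,
) -> dict:
    """Spearman rank correlation between mean C and mean N across genomes,
    with per-group means when labels are given. A constant vector leaves the
    correlation undefined (NaN, flagged)."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    c = np.array([p.mean_c_per_aa for p in profiles])
    n = np.array([p.mean_n_per_aa for p in profiles])
    if np.allclose(c, c[0]) or np.allclose(n, n[0]):
        rho, p = math.nan, math.nan
    else:
        res = stats.spearmanr(c, n)
        rho, p = float(res.statistic), float(res.pvalue)
    out = {"rho": rho, "p_value": p, "n": len(profiles)}
    if group_labels is not None:
        df = pd.DataFrame(
            {"group": list(group_labels), "mean_c": c, "mean_n": n}
        )
        out["group_means"] = (
            df.groupby("group", sort=False)[["mean_c", "mean_n"]].mean()
        )
    return out


def elements_table(
    profiles: Sequence[ElementalProfile],
    lineages: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rows = [
        {
            "genome_id": p.genome_id,
            "lineage": (lineages or {}).get(p.genome_id, ""),
            "mean_c_per_aa": p.mean_c_per_aa,
            "mean_n_per_aa": p.mean_n_per_aa,
            "weighted_c_per_aa": p.weighted_c_per_aa,
            "weighted_n_per_aa": p.weighted_n_per_aa,
            "n_proteins": p.n_proteins,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
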