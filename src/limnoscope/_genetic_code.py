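"""Shared genetic-code constants (bacterial translation table 11)."""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

#: all 64 codons in lexicographic (A<C<G<T) order — the canonical row order
#: of every codon matrix this package writes.
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product("ACGT", repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_TABLE = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in CODONS if c not in STOP_CODONS
)

#: codon -> one-letter amino acid (sense codons only)
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

#: standard residues in alphabetical one-letter order — the canonical row
#: order of every amino-acid table this package writes.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

#: amino acid -> tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AA_ORDER
}

#: amino acids whose synonymous family varies at the third position
#: (all standard residues except Met and Trp): 18 families.
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa, codons in AA_TO_CODONS.items() if len(codons) > 1
)

#: codons whose third base is G or C
GC3_CODONS: frozenset[str] = frozenset(c for c in CODONS if c[2] in "GC")
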