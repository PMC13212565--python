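"""Synthetic genomes, proteomes, KO tables, trees and abundance tables.

The generator emulates the study contrasts the analysis modules are built
to detect: lineages with contrasting genome size and GC content, genic vs
intergenic GC structure, a progressive GC-rich -> AT-rich synonymous codon
replacement along lineage order, amino-acid usage shifted toward
carbon/nitrogen-cheap residues in one lineage, habitat-structured KO pools
with controlled overlap and redundancy, and a pure-birth tree with known
branch lengths. Every generated quantity has a downstream estimator, so the
whole pipeline is testable by parameter recovery without any downloads.

Determinism: one root seed; per-genome streams are derived by stable
hashing of the genome id, so adding a genome never perturbs the others.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from Bio.Seq import Seq
from scipy.optimize import brentq

from ._genetic_code import (
    AA_INDEX,
    AA_ORDER,
    AA_TO_CODONS,
    CODON_INDEX,
    CODONS,
    DEGENERATE_AAS,
    GC3_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
)
from .core_io import HABITATS, AnnotationTable, GeneCoord, GenomeRecord

__all__ = [
    "LineageSpec",
    "SimulationConfig",
    "SimBundle",
    "gen_codon_usage",
    "codon_usage_for_genic_gc",
    "gen_genome",
    "gen_ko_table",
    "designed_jaccard",
    "gen_tree",
    "gen_abundance_table",
    "simulate",
    "write_bundle",
    "study_lineages",
    "study_config",
    "derive_seed",
    "aa_marginals",
    "gc3_fraction",
    "expected_gc_fraction",
]

_GC_PER_CODON = np.array([sum(b in "GC" for b in c) for c in CODONS], float)
_IS_GC3 = np.array([c in GC3_CODONS for c in CODONS], float)
_SENSE_IDX = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
_SENSE_ARR = np.array(SENSE_CODONS)

#: mean GC fraction of a terminal stop codon drawn uniformly from
#: {TAA, TAG, TGA}: (0 + 1 + 1) / 3 GC bases over 3 positions.
_STOP_GC_FRACTION = 2.0 / 9.0


def derive_seed(root_seed: int, name: str) -> int:
    """Stable per-stream seed below 2**31, derived from a root seed."""
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


# ---------------------------------------------------------------------------
# Codon usage construction


def aa_marginals(usage: np.ndarray) -> np.ndarray:
    """Amino-acid marginal probabilities implied by a 64-codon usage vector."""
    usage = np.asarray(usage, float)
    out = np.zeros(len(AA_ORDER))
    for aa, codons in AA_TO_CODONS.items():
        out[AA_INDEX[aa]] = sum(usage[CODON_INDEX[c]] for c in codons)
    return out


def gc3_fraction(usage: np.ndarray) -> float:
    """Expected third-position G+C share under a 64-codon usage vector."""
    usage = np.asarray(usage, float)
    return float((usage * _IS_GC3).sum() / usage.sum())


def expected_gc_fraction(usage: np.ndarray) -> float:
    """Expected per-base GC fraction of codons drawn from ``usage``."""
    usage = np.asarray(usage, float)
    return float((usage * _GC_PER_CODON).sum() / (3.0 * usage.sum()))


def _reweight_by_gc3(base: np.ndarray, x: float) -> np.ndarray:
    """Multiply GC-ending codons by ``x`` within each synonymous family,
    renormalizing per family so amino-acid marginals are unchanged.
    Met, Trp (no third-position degeneracy) and stop codons are untouched.
    """
    out = base.copy()
    for aa in DEGENERATE_AAS:
        idx = np.array([CODON_INDEX[c] for c in AA_TO_CODONS[aa]])
        mass = base[idx].sum()
        if mass <= 0:
            continue
        w = base[idx] * np.where(_IS_GC3[idx] > 0, x, 1.0)
        out[idx] = mass * w / w.sum()
    return out


def gen_codon_usage(gc3_level: float, base_usage: np.ndarray) -> np.ndarray:
    """Reallocate synonymous-codon mass so the expected third-position G+C
    equals ``gc3_level`` while amino-acid marginals are unchanged.

    Raises ``ValueError`` when ``gc3_level`` lies outside the range reachable
    by third-position reweighting (the floor/ceiling set by nondegenerate
    codons and by synonymous codons absent from ``base_usage``).
    """
    if not (0 < gc3_level < 1):
        raise ValueError(f"gc3_level must be in (0, 1), got {gc3_level}")
    base = np.asarray(base_usage, float)
    if base.shape != (64,):
        raise ValueError("base_usage must be a 64-vector")
    if abs(base.sum() - 1.0) > 1e-6:
        raise ValueError("base_usage must sum to 1")
    if abs(gc3_fraction(base) - gc3_level) < 1e-12:
        return base.copy()

    def objective(logx: float) -> float:
        return gc3_fraction(_reweight_by_gc3(base, float(np.exp(logx)))) - gc3_level

    lo, hi = -60.0, 60.0
    if objective(lo) > 0 or objective(hi) < 0:
        raise ValueError(
            f"gc3_level={gc3_level} unreachable: attainable range is "
            f"[{gc3_fraction(_reweight_by_gc3(base, np.exp(lo))):.4f}, "
            f"{gc3_fraction(_reweight_by_gc3(base, np.exp(hi))):.4f}]"
        )
    logx = brentq(objective, lo, hi, xtol=1e-13)
    return _reweight_by_gc3(base, float(np.exp(logx)))


def _uniform_family_usage(aa_usage: np.ndarray) -> np.ndarray:
    """Spread each amino acid's mass uniformly over its synonymous codons."""
    out = np.zeros(64)
    for aa, codons in AA_TO_CODONS.items():
        share = aa_usage[AA_INDEX[aa]] / len(codons)
        for c in codons:
            out[CODON_INDEX[c]] = share
    return out


def codon_usage_for_genic_gc(
    aa_usage: np.ndarray | Mapping[str, float],
    genic_gc_target: float,
    mean_gene_codons: int = 300,
) -> np.ndarray:
    """Construct a 64-codon usage whose genes hit a genic GC target.

    Starting from ``aa_usage`` spread uniformly within synonymous families,
    a single third-position reweighting multiplier is solved so the expected
    GC of a gene of ``mean_gene_codons`` codons (one of which is a uniform
    terminal stop) equals ``genic_gc_target``. Amino-acid marginals are
    preserved exactly.
    """
    if isinstance(aa_usage, Mapping):
        vec = np.zeros(len(AA_ORDER))
        for aa, p in aa_usage.items():
            vec[AA_INDEX[aa]] = p
        aa_usage = vec
    aa_usage = np.asarray(aa_usage, float)
    aa_usage = aa_usage / aa_usage.sum()
    base = _uniform_family_usage(aa_usage)
    k = mean_gene_codons

    def gene_gc(usage: np.ndarray) -> float:
        sense = expected_gc_fraction(usage)
        return ((k - 1) * sense + _STOP_GC_FRACTION) / k

    def objective(logx: float) -> float:
        return gene_gc(_reweight_by_gc3(base, float(np.exp(logx)))) - genic_gc_target

    lo, hi = -60.0, 60.0
    if objective(lo) > 0 or objective(hi) < 0:
        raise ValueError(
            f"genic GC target {genic_gc_target} unreachable for this "
            f"amino-acid usage: attainable range is "
            f"[{gene_gc(_reweight_by_gc3(base, np.exp(lo))):.4f}, "
            f"{gene_gc(_reweight_by_gc3(base, np.exp(hi))):.4f}]"
        )
    logx = brentq(objective, lo, hi, xtol=1e-13)
    return _reweight_by_gc3(base, float(np.exp(logx)))


# ---------------------------------------------------------------------------
# Lineage specifications


@dataclass
class LineageSpec:
    """Ground-truth parameters for one synthetic lineage."""

    name: str
    n_genomes: int
    genome_size_bp: tuple[float, float]       # mean, sd
    gene_length_bp: tuple[float, float]       # mean (multiple of 3), sd
    intergenic_length_bp: tuple[float, float]  # mean, sd
    codon_usage: np.ndarray                    # 64-vector, stop mass 0
    intergenic_gc_target: float
    habitat: str = "other"
    ko_pool: frozenset[str] = frozenset()
    ko_redundancy: float = 0.0                 # expected FRR
    sigma_factor_rate: float = 0.0             # sigma genes per 1000 genes
    completeness_range: tuple[float, float] = (100.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.codon_usage = np.asarray(self.codon_usage, float)
        if self.codon_usage.shape != (64,):
            raise ValueError(f"{self.name}: codon_usage must be a 64-vector")
        if abs(self.codon_usage.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: codon_usage must sum to 1")
        for stop in STOP_CODONS:
            if self.codon_usage[CODON_INDEX[stop]] > 0:
                raise ValueError(
                    f"{self.name}: stop codons carry usage mass; stops are "
                    "emitted only terminally"
                )
        if not (0 < self.intergenic_gc_target < 1):
            raise ValueError(f"{self.name}: intergenic_gc_target not in (0, 1)")
        if not (0 <= self.ko_redundancy < 1):
            raise ValueError(f"{self.name}: ko_redundancy must be in [0, 1)")
        if self.gene_length_bp[0] % 3:
            raise ValueError(f"{self.name}: mean gene length must be a multiple of 3")
        if self.habitat not in HABITATS:
            raise ValueError(f"{self.name}: unknown habitat {self.habitat!r}")

    @property
    def aa_usage(self) -> np.ndarray:
        """Amino-acid marginals implied by the codon usage (sums to 1)."""
        return aa_marginals(self.codon_usage)

    @property
    def mean_gene_codons(self) -> int:
        return int(self.gene_length_bp[0] // 3)

    @property
    def genic_gc_target(self) -> float:
        """Expected GC fraction of genes, terminal stop codon included."""
        k = self.mean_gene_codons
        sense = expected_gc_fraction(self.codon_usage)
        return ((k - 1) * sense + _STOP_GC_FRACTION) / k

    def genome_ids(self) -> list[str]:
        return [f"{self.name}_g{i:03d}" for i in range(self.n_genomes)]


# ---------------------------------------------------------------------------
# Genome generation


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def gen_genome(
    spec: LineageSpec,
    rng: np.random.Generator,
    flip_strands: bool = False,
) -> tuple[GenomeRecord, dict[str, str], dict[str, str]]:
    """Emit one genome: a single linear contig of alternating genes and
    intergenic tracts, plus its CDS and translated protein sets.

    Genes are sampled codon-by-codon from ``spec.codon_usage`` and closed by
    a uniform terminal stop; intergenic tracts are i.i.d. bases at the
    intergenic GC target. With ``flip_strands`` each gene lands on '-' with
    probability 1/2 (the genomic segment is reverse-complemented; the
    returned CDS is always the coding strand).
    """
    gene_mean, gene_sd = spec.gene_length_bp
    ig_mean, ig_sd = spec.intergenic_length_bp
    if gene_mean < 6:
        raise ValueError(f"{spec.name}: mean gene length < 6 bp is infeasible")
    size_mean = spec.genome_size_bp[0]
    n_genes = max(1, int(round(size_mean / (gene_mean + ig_mean))))

    sense_p = spec.codon_usage[_SENSE_IDX]
    sense_p = sense_p / sense_p.sum()

    genome_id = spec.name  # caller renames via _build_genome in simulate()
    return _emit_genome(
        genome_id, spec, rng, n_genes, sense_p, flip_strands
    )


def _emit_genome(
    genome_id: str,
    spec: LineageSpec,
    rng: np.random.Generator,
    n_genes: int,
    sense_p: np.ndarray,
    flip_strands: bool,
) -> tuple[GenomeRecord, dict[str, str], dict[str, str]]:
    gene_mean, gene_sd = spec.gene_length_bp
    ig_mean, ig_sd = spec.intergenic_length_bp
    contig_id = f"{genome_id}_c1"

    parts: list[str] = []
    genes: list[GeneCoord] = []
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    pos = 1

    def intergenic() -> None:
        nonlocal pos
        n = max(0, int(round(rng.normal(ig_mean, ig_sd))))
        if n:
            parts.append(_random_bases(n, spec.intergenic_gc_target, rng))
            pos += n

    intergenic()  # leading terminal flank
    for i in range(n_genes):
        n_codons = max(2, int(round(rng.normal(gene_mean, gene_sd) / 3)))
        body_idx = rng.choice(len(sense_p), size=n_codons - 1, p=sense_p)
        stop = STOP_CODONS[int(rng.integers(3))]
        seq = "".join(_SENSE_ARR[body_idx]) + stop
        gene_id = f"{genome_id}_{i + 1:05d}"
        strand = "-" if flip_strands and rng.random() < 0.5 else "+"
        parts.append(
            str(Seq(seq).reverse_complement()) if strand == "-" else seq
        )
        is_sigma = rng.random() < spec.sigma_factor_rate / 1000.0
        genes.append(
            GeneCoord(
                gene_id=gene_id,
                contig_id=contig_id,
                start=pos,
                end=pos + len(seq) - 1,
                strand=strand,
                product_class="sigma_factor" if is_sigma else "other",
            )
        )
        cds[gene_id] = seq
        proteins[gene_id] = str(Seq(seq[:-3]).translate(table=11))
        pos += len(seq)
        intergenic()  # internal spacer, or trailing flank after last gene

    record = GenomeRecord(
        genome_id=genome_id,
        contigs={contig_id: "".join(parts)},
        genes=genes,
        completeness_pct=float(rng.uniform(*spec.completeness_range)),
        contamination_pct=float(rng.uniform(*spec.contamination_range)),
        habitat=spec.habitat,
        lineage=spec.name,
    )
    return record, cds, proteins


def fragment(
    record: GenomeRecord, k: int, rng: np.random.Generator
) -> GenomeRecord:
    """Split a one-contig genome into ``k`` contigs at intergenic midpoints.

    Robustness utility: fragmentation is orthogonal to every statistic this
    package computes, so metrics should be invariant under it (up to the
    internal-vs-terminal spacer partition).
    """
    if len(record.contigs) != 1:
        raise ValueError("fragment() expects a single-contig genome")
    (contig_id, seq), = record.contigs.items()
    genes = sorted(record.genes, key=lambda g: g.start)
    gaps = []  # candidate cut points: midpoints of internal spacers
    for a, b in zip(genes, genes[1:]):
        if b.start > a.end + 1:
            gaps.append((a.end + 1 + b.start - 1) // 2)
    if k - 1 > len(gaps):
        raise ValueError(f"cannot cut into {k} contigs: only {len(gaps)} spacers")
    cuts = sorted(rng.choice(len(gaps), size=k - 1, replace=False))
    cut_pos = [gaps[i] for i in cuts]
    bounds = [0, *cut_pos, len(seq)]
    contigs = {}
    new_genes = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        cid = f"{record.genome_id}_c{i + 1}"
        contigs[cid] = seq[lo:hi]
        for g in genes:
            if lo < g.start <= hi:
                new_genes.append(
                    GeneCoord(
                        gene_id=g.gene_id, contig_id=cid,
                        start=g.start - lo, end=g.end - lo,
                        strand=g.strand, product_class=g.product_class,
                    )
                )
    return GenomeRecord(
        genome_id=record.genome_id, contigs=contigs, genes=new_genes,
        completeness_pct=record.completeness_pct,
        contamination_pct=record.contamination_pct,
        habitat=record.habitat, lineage=record.lineage,
    )


# ---------------------------------------------------------------------------
# KO tables


def _check_disjoint_pools(
    shared_core: frozenset[str], habitat_specific: Mapping[str, frozenset[str]]
) -> None:
    labels = sorted(habitat_specific)
    for i, a in enumerate(labels):
        inter = shared_core & frozenset(habitat_specific[a])
        if inter:
            raise ValueError(
                f"habitat-specific pool {a!r} overlaps the shared core: "
                f"{sorted(inter)[:5]}"
            )
        for b in labels[i + 1:]:
            inter = frozenset(habitat_specific[a]) & frozenset(habitat_specific[b])
            if inter:
                raise ValueError(
                    f"'specific' pools {a!r} and {b!r} overlap: "
                    f"{sorted(inter)[:5]}"
                )


def designed_jaccard(
    shared_core: frozenset[str],
    habitat_specific: Mapping[str, frozenset[str]],
) -> dict[tuple[str, str], float]:
    """The Jaccard matrix the generated habitat pools will reproduce exactly."""
    _check_disjoint_pools(frozenset(shared_core), habitat_specific)
    pools = {
        h: frozenset(shared_core) | frozenset(s)
        for h, s in habitat_specific.items()
    }
    out = {}
    for a in pools:
        for b in pools:
            union = pools[a] | pools[b]
            out[(a, b)] = (
                len(pools[a] & pools[b]) / len(union) if union else 0.0
            )
    return out


def gen_ko_table(
    genome_habitats: Mapping[str, str],
    shared_core: frozenset[str],
    habitat_specific: Mapping[str, frozenset[str]],
    redundancy: float | Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, AnnotationTable]:
    """One AnnotationTable per genome with designed habitat structure.

    Every genome carries its habitat's full pool (shared core plus the
    habitat-specific set) as distinct KOs, so pooled habitat sets reproduce
    the designed Jaccard matrix exactly. Duplicate annotations are injected
    at the count d = round(u*f/(1-f)) that realizes an expected functional
    redundancy ratio f for a genome with u distinct KOs.
    """
    _check_disjoint_pools(frozenset(shared_core), habitat_specific)
    tables: dict[str, AnnotationTable] = {}
    for genome_id in sorted(genome_habitats):
        habitat = genome_habitats[genome_id]
        pool = sorted(frozenset(shared_core) | frozenset(habitat_specific.get(habitat, frozenset())))
        f = redundancy[habitat] if isinstance(redundancy, Mapping) else redundancy
        if not (0 <= f < 1):
            raise ValueError(f"redundancy must be in [0, 1), got {f}")
        u = len(pool)
        n_dup = int(round(u * f / (1 - f)))
        dups = (
            list(np.array(pool)[rng.integers(0, u, size=n_dup)]) if n_dup else []
        )
        kos = pool + dups
        annotations = [
            (f"{genome_id}_{i + 1:05d}", ko) for i, ko in enumerate(kos)
        ]
        tables[genome_id] = AnnotationTable(genome_id, annotations)
    return tables


# ---------------------------------------------------------------------------
# Trees


def _yule_subtree(
    labels: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    tns: dendropy.TaxonNamespace,
) -> dendropy.Node:
    """Pure-birth subtree over ``labels``; the root edge length is left for
    the caller to set (it is the stem of the clade)."""
    root = dendropy.Node()
    root._birth = 0.0
    active = [root]
    t = 0.0
    while len(active) < len(labels):
        t += rng.exponential(1.0 / (rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.edge.length = t - parent._birth
        for _ in range(2):
            child = dendropy.Node()
            child._birth = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (rate * len(active)))
    for leaf, label in zip(active, labels):
        leaf.edge.length = t - leaf._birth
        leaf.taxon = tns.require_taxon(label)
    return root


def gen_tree(
    tips_per_lineage: Mapping[str, Sequence[str] | int],
    rate: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Pure-birth tree with monophyletic lineages on a ladder backbone.

    ``tips_per_lineage`` maps lineage name (oldest first) to tip labels or a
    tip count (labels then default to ``{name}_g{i:03d}``). All branch
    lengths are positive exponential draws at the given birth rate; the root
    edge has length 0.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    tns = dendropy.TaxonNamespace()
    subtrees = []
    for name, tips in tips_per_lineage.items():
        labels = (
            [f"{name}_g{i:03d}" for i in range(tips)]
            if isinstance(tips, int)
            else list(tips)
        )
        if not labels:
            raise ValueError(f"lineage {name!r} has no tips")
        subtrees.append(_yule_subtree(labels, rate, rng, tns))

    if len(subtrees) == 1:
        root = subtrees[0]
    else:
        root = dendropy.Node()
        cur = root
        for i in range(len(subtrees) - 1):
            subtrees[i].edge.length = float(rng.exponential(1.0 / rate))
            cur.add_child(subtrees[i])
            if i < len(subtrees) - 2:
                nxt = dendropy.Node()
                nxt.edge.length = float(rng.exponential(1.0 / rate))
                cur.add_child(nxt)
                cur = nxt
            else:
                subtrees[-1].edge.length = float(rng.exponential(1.0 / rate))
                cur.add_child(subtrees[-1])
    root.edge.length = 0.0
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Abundance tables


def gen_abundance_table(
    family_habitat_profile: Mapping[str, Mapping[str, float]],
    n_samples: int,
    noise: float,
    rng: np.random.Generator,
    median_abundance_pct: float = 2.0,
) -> "pd.DataFrame":
    """Relative-abundance rows with habitat draws following each family's
    profile multinomially and abundances drawn log-normally.

    The abundance of each (sample, family) match is
    ``min(100, LogNormal(log(median_abundance_pct), noise))`` — strictly
    positive, right-skewed, occasionally reaching the two-digit peak
    abundances the habitat summaries report.
    """
    import pandas as pd

    rows = []
    for taxon in sorted(family_habitat_profile):
        profile = family_habitat_profile[taxon]
        habitats = sorted(profile)
        probs = np.array([profile[h] for h in habitats], float)
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"profile for {taxon!r} must sum to 1")
        draws = rng.choice(len(habitats), size=n_samples, p=probs)
        abund = np.minimum(
            100.0,
            rng.lognormal(np.log(median_abundance_pct), noise, size=n_samples),
        )
        for i, (h, a) in enumerate(zip(draws, abund)):
            rows.append((f"{taxon}_s{i:05d}", habitats[h], taxon, float(a)))
    return pd.DataFrame(
        rows, columns=["sample_id", "habitat", "taxon", "rel_abundance_pct"]
    )


# ---------------------------------------------------------------------------
# Study conditions

#: per-lineage medians the generator emulates (name, relative genome size,
#: genic GC, intergenic GC, spacer mean/sd bp, sigma rate per 1000 genes,
#: expected FRR, habitat)
_BASELINE_AA_USAGE = {
    "A": 0.120, "R": 0.065, "N": 0.025, "D": 0.060, "C": 0.008,
    "Q": 0.030, "E": 0.070, "G": 0.090, "H": 0.020, "I": 0.040,
    "L": 0.110, "K": 0.025, "M": 0.020, "F": 0.035, "P": 0.050,
    "S": 0.050, "T": 0.065, "V": 0.085, "W": 0.012, "Y": 0.020,
}

#: the reduced lineage's usage, shifted toward carbon/nitrogen-cheap
#: residues (Gly/Ala/Ser gain what Arg/Lys/His/Phe/Trp lose)
_ECONOMIZED_AA_USAGE = {
    **_BASELINE_AA_USAGE,
    "G": 0.125, "A": 0.150, "S": 0.070,
    "R": 0.040, "K": 0.015, "H": 0.012, "F": 0.025, "W": 0.006,
    "L": 0.092,
}

KO_SHARED_CORE = frozenset(f"K{i:05d}" for i in range(1, 401))
KO_HABITAT_SPECIFIC = {
    "soil": frozenset(f"K{i:05d}" for i in range(1000, 1100)),
    "sediment": frozenset(f"K{i:05d}" for i in range(2000, 2150)),
    "freshwater": frozenset(f"K{i:05d}" for i in range(3000, 3300)),
}

HABITAT_PROFILES = {
    "P2-11E": {"soil": 0.945, "sediment": 0.025, "freshwater": 0.030},
    "QHBO01": {"soil": 0.928, "sediment": 0.040, "freshwater": 0.032},
    "CSP1-4": {"soil": 0.714, "sediment": 0.250, "freshwater": 0.036},
    "Limnocylindraceae": {"soil": 0.013, "freshwater": 0.987},
}


def study_lineages(
    n_genomes: int = 20, genes_reference: int = 200
) -> list[LineageSpec]:
    """The four default lineages, oldest first.

    Genome-size contrast follows the 3.2/2.8/2.4/1.3 Mbp family medians with
    gene counts scaled so the largest lineage carries ``genes_reference``
    genes; genic GC targets are 68.6/68.0/68.0/63.15 %; the reduced lineage
    has GC-richer intergenic spacers (66 %) with a 12 bp mean spacer length,
    an amino-acid usage shifted toward C/N-cheap residues, fewer sigma
    factors, and a freshwater habitat. Completeness and contamination ranges
    are centered on 80 % and 1.6 %.
    """
    rows = [
        # name, rel size, genic GC, intergenic GC, spacer (mean, sd), sigma, FRR
        ("P2-11E", 3.2, 0.686, 0.630, (160.0, 60.0), 9.0, 0.05, "soil",
         _BASELINE_AA_USAGE),
        ("QHBO01", 2.8, 0.680, 0.630, (150.0, 60.0), 9.0, 0.08, "soil",
         _BASELINE_AA_USAGE),
        ("CSP1-4", 2.4, 0.680, 0.640, (200.0, 80.0), 10.0, 0.30, "sediment",
         _BASELINE_AA_USAGE),
        ("Limnocylindraceae", 1.3, 0.6315, 0.660, (12.0, 6.0), 3.0, 0.10,
         "freshwater", _ECONOMIZED_AA_USAGE),
    ]
    gene_mean, gene_sd = 900.0, 240.0
    specs = []
    for name, rel, ggc, igc, (ig_mean, ig_sd), sigma, frr, habitat, aa in rows:
        n_genes = max(10, int(round(genes_reference * rel / 3.2)))
        usage = codon_usage_for_genic_gc(aa, ggc, int(gene_mean // 3))
        size_mean = n_genes * (gene_mean + ig_mean)
        specs.append(
            LineageSpec(
                name=name,
                n_genomes=n_genomes,
                genome_size_bp=(size_mean, 0.05 * size_mean),
                gene_length_bp=(gene_mean, gene_sd),
                intergenic_length_bp=(ig_mean, ig_sd),
                codon_usage=usage,
                intergenic_gc_target=igc,
                habitat=habitat,
                ko_pool=frozenset(KO_SHARED_CORE)
                | KO_HABITAT_SPECIFIC.get(habitat, frozenset()),
                ko_redundancy=frr,
                sigma_factor_rate=sigma,
                completeness_range=(70.0, 95.0),
                contamination_range=(0.0, 5.0),
            )
        )
    return specs


def gradient_lineages(
    gc3_levels: Sequence[float],
    n_genomes: int = 12,
    n_genes: int = 40,
    gene_length: tuple[float, float] = (300.0, 30.0),
) -> list[LineageSpec]:
    """Ordered lineages differing only in third-position GC, for studying
    progressive synonymous GC->AT codon replacement along a lineage series.

    Starts from a uniform codon usage (equal mass per amino acid family)
    and reweights each lineage to its gc3 level; amino-acid marginals are
    identical across the series, so any between-lineage shift in codon
    frequencies is purely synonymous.
    """
    base = _uniform_family_usage(np.full(len(AA_ORDER), 1.0 / len(AA_ORDER)))
    specs = []
    for k, level in enumerate(gc3_levels):
        specs.append(
            LineageSpec(
                name=f"L{k}",
                n_genomes=n_genomes,
                genome_size_bp=(n_genes * (gene_length[0] + 12.0), 500.0),
                gene_length_bp=gene_length,
                intergenic_length_bp=(12.0, 4.0),
                codon_usage=gen_codon_usage(level, base),
                intergenic_gc_target=0.5,
                habitat="soil",
            )
        )
    return specs


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a fixture bundle byte-identically."""

    lineages: list[LineageSpec]
    seed: int
    tree_rate: float = 2.0
    n_abundance_samples: int = 1000
    abundance_noise: float = 1.0
    shared_core: frozenset[str] = KO_SHARED_CORE
    habitat_specific: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(KO_HABITAT_SPECIFIC)
    )
    habitat_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(HABITAT_PROFILES)
    )
    flip_strands: bool = False


def study_config(
    seed: int,
    n_genomes: int = 20,
    genes_reference: int = 200,
    n_abundance_samples: int = 1000,
) -> SimulationConfig:
    lineages = study_lineages(n_genomes, genes_reference)
    return SimulationConfig(
        lineages=lineages,
        seed=seed,
        n_abundance_samples=n_abundance_samples,
    )


def config_from_yaml(path: str) -> SimulationConfig:
    """Load a simulation config; unspecified fields take study defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = study_config(
        seed=int(raw.get("seed", 0)),
        n_genomes=int(raw.get("n_genomes", 20)),
        genes_reference=int(raw.get("genes_reference", 200)),
        n_abundance_samples=int(raw.get("n_abundance_samples", 1000)),
    )
    if "tree_rate" in raw:
        cfg.tree_rate = float(raw["tree_rate"])
    if "abundance_noise" in raw:
        cfg.abundance_noise = float(raw["abundance_noise"])
    if "flip_strands" in raw:
        cfg.flip_strands = bool(raw["flip_strands"])
    return cfg


@dataclass
class SimBundle:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    genomes: list[GenomeRecord]
    cds: dict[str, dict[str, str]]          # genome_id -> gene_id -> CDS
    proteins: dict[str, dict[str, str]]
    annotations: dict[str, AnnotationTable]
    tree: dendropy.Tree
    abundance: "pd.DataFrame"

    def genomes_by_lineage(self) -> dict[str, list[GenomeRecord]]:
        out: dict[str, list[GenomeRecord]] = {}
        for g in self.genomes:
            out.setdefault(g.lineage, []).append(g)
        return out


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate the full fixture bundle under one root seed."""
    genomes: list[GenomeRecord] = []
    cds: dict[str, dict[str, str]] = {}
    proteins: dict[str, dict[str, str]] = {}
    genome_habitats: dict[str, str] = {}
    for spec in config.lineages:
        for genome_id in spec.genome_ids():
            rng = np.random.default_rng(derive_seed(config.seed, genome_id))
            n_genes = max(
                1,
                int(round(
                    spec.genome_size_bp[0]
                    / (spec.gene_length_bp[0] + spec.intergenic_length_bp[0])
                )),
            )
            sense_p = spec.codon_usage[_SENSE_IDX]
            sense_p = sense_p / sense_p.sum()
            record, gcds, gprot = _emit_genome(
                genome_id, spec, rng, n_genes, sense_p, config.flip_strands
            )
            genomes.append(record)
            cds[genome_id] = gcds
            proteins[genome_id] = gprot
            genome_habitats[genome_id] = spec.habitat

    ko_rng = np.random.default_rng(derive_seed(config.seed, "ko_tables"))
    redundancy = {}
    for spec in config.lineages:
        for genome_id in spec.genome_ids():
            redundancy[genome_id] = spec.ko_redundancy
    annotations = _gen_ko_per_genome(
        genome_habitats, config.shared_core, config.habitat_specific,
        redundancy, ko_rng,
    )

    tree_rng = np.random.default_rng(derive_seed(config.seed, "tree"))
    tree = gen_tree(
        {spec.name: spec.genome_ids() for spec in config.lineages},
        config.tree_rate,
        tree_rng,
    )

    ab_rng = np.random.default_rng(derive_seed(config.seed, "abundance"))
    profiles = {
        spec.name: config.habitat_profiles.get(
            spec.name, {spec.habitat: 1.0}
        )
        for spec in config.lineages
    }
    abundance = gen_abundance_table(
        profiles, config.n_abundance_samples, config.abundance_noise, ab_rng
    )
    return SimBundle(
        config=config, genomes=genomes, cds=cds, proteins=proteins,
        annotations=annotations, tree=tree, abundance=abundance,
    )


def _gen_ko_per_genome(
    genome_habitats: Mapping[str, str],
    shared_core: frozenset[str],
    habitat_specific: Mapping[str, frozenset[str]],
    redundancy: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, AnnotationTable]:
    # like gen_ko_table, but redundancy keyed per genome (lineage-specific FRR)
    _check_disjoint_pools(frozenset(shared_core), habitat_specific)
    tables: dict[str, AnnotationTable] = {}
    for genome_id in sorted(genome_habitats):
        habitat = genome_habitats[genome_id]
        pool = sorted(
            frozenset(shared_core)
            | frozenset(habitat_specific.get(habitat, frozenset()))
        )
        f = redundancy[genome_id]
        u = len(pool)
        n_dup = int(round(u * f / (1 - f)))
        dups = (
            list(np.array(pool)[rng.integers(0, u, size=n_dup)]) if n_dup else []
        )
        kos = pool + dups
        tables[genome_id] = AnnotationTable(
            genome_id,
            [(f"{genome_id}_{i + 1:05d}", ko) for i, ko in enumerate(kos)],
        )
    return tables


def write_bundle(bundle: SimBundle, out_dir: str) -> dict:
    """Write the bundle as plain-text files and return a manifest dict."""
    import json
    from pathlib import Path

    from . import core_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for record in bundle.genomes:
        core_io.write_fasta(record.contigs, out / f"{record.genome_id}.fna")
        core_io.write_fasta(
            bundle.cds[record.genome_id], out / f"{record.genome_id}.ffn"
        )
        core_io.write_fasta(
            bundle.proteins[record.genome_id], out / f"{record.genome_id}.faa"
        )
    core_io.write_gene_table(bundle.genomes, out / "genes.tsv")
    core_io.write_metadata(bundle.genomes, out / "metadata.tsv")
    core_io.write_annotation_tables(
        bundle.annotations.values(), out / "annotations.tsv"
    )
    core_io.write_tree(bundle.tree, out / "tree.nwk")
    bundle.abundance.to_csv(out / "abundance.tsv", sep="\t", index=False)

    truth = {
        spec.name: {
            "n_genomes": spec.n_genomes,
            "genic_gc_target_pct": 100 * spec.genic_gc_target,
            "intergenic_gc_target_pct": 100 * spec.intergenic_gc_target,
            "gene_length_bp": list(spec.gene_length_bp),
            "intergenic_length_bp": list(spec.intergenic_length_bp),
            "sigma_factor_rate": spec.sigma_factor_rate,
            "ko_redundancy": spec.ko_redundancy,
            "habitat": spec.habitat,
            "aa_usage": dict(zip(AA_ORDER, map(float, spec.aa_usage))),
        }
        for spec in bundle.config.lineages
    }
    manifest = {
        "seed": bundle.config.seed,
        "n_genomes_total": len(bundle.genomes),
        "tree_tips": len(bundle.tree.leaf_nodes()),
        "abundance_rows": int(len(bundle.abundance)),
        "ground_truth": truth,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
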