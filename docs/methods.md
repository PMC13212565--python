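# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model and conventions

Gene coordinates are 1-based inclusive (GFF3 convention); gene tables are
headered TSV rather than full GFF3 to avoid attribute-dialect parsing,
with a thin GFF3 importer that maps columns 1/4/5/7 and the `ID`
attribute. Sequences accept A/C/G/T, N and the IUPAC ambiguity codes;
anything else is a validation error that names the offending symbols.
Parsers never silently drop records. A missing Newick root-edge length is
read as 0; negative branch lengths are rejected at parse time. Matrix
output renders floats at 6 significant digits, which bounds write→read
round-trip error at 1e-6 relative. Partial genes at contig edges are
accepted as ordinary genes: with coordinates as the only evidence there
is no reliable way to distinguish them, and every downstream statistic is
insensitive to the distinction.

## Genome architecture

**Corrected genome size.** `L × (100/completeness) × ((100−contam)/100)`:
the assembled length is scaled up for estimated missing content and down
for contamination. Completeness must be in (0, 100], contamination in
[0, 100). The correction is arithmetic only — no re-assembly is implied,
which is also why the generator treats completeness/contamination as
metadata rather than actually deleting sequence.

**GC.** GC percent is computed over unambiguous bases only; N and
ambiguity codes are excluded from numerator and denominator, and a
sequence with no countable base yields a missing value rather than 0. GC
is strand-symmetric, so no reverse-complementing is done for GC-type
metrics.

**Genic/intergenic partition.** Gene intervals are merged once
(overlapping or book-ended intervals form one genic run) before density
and spacer computation; this keeps coding density in [0, 1] and makes
genic + intergenic account for every assembled base. Internal spacers
are maximal non-genic runs strictly between merged genes on one contig;
contig-terminal flanks are artifacts of where the assembly starts and
ends, so they are reported separately and excluded from spacer medians.

**Sigma-factor rate.** Normalized per 1000 genes (the denominator could
equally be Mbp; genes were chosen because regulatory capacity scales with
gene repertoire, and the choice is localized in one function).

## Codon and amino-acid composition

Codon counting walks each CDS on the coding strand in frames of three,
pooling counts per genome. Trailing 1–2 nt remainders and triplets
containing non-ACGT characters are dropped, not imputed; dropped counts
are kept on the profile for auditability. Stop codons are counted in the
64-codon table but excluded from the synonymous-family trend, which
concerns amino-acid-preserving replacement. Terminal stops are trimmed by
the stated rule: drop the final triplet iff it is TAA/TAG/TGA.

The funnel summary operationalizes a qualitative observation — ancestral
GC-rich codons progressively replaced by AT-rich ones — as, per
synonymous family with third-position degeneracy (18 families: all
standard residues except Met and Trp), the per-group mean within-family
share of G/C-ending codons, its Kendall trend sign across the ordered
groups, and the fraction of families declining monotonically.

## Proteome C/N stoichiometry

Atom counts per residue use the side-chain-inclusive molecular formulas
of the free amino acids (G: C2N1 … R: C6N4, W: C11N2). Peptide-bond
condensation removes only H2O, so C and N per residue are identical
between free-acid and residue formulas; this is documented to preempt
formula disputes. Nonstandard symbols (X/B/Z/U/*) are excluded from both
atom sums and length. The proteome mean is the unweighted arithmetic mean
over proteins of per-protein atoms-per-residue (normalize-then-average);
the residue-weighted alternative (total atoms / total residues) is
computed alongside because the two differ when composition covaries with
protein length, but unweighted is primary. The C–N relationship across
genomes uses Spearman's rank correlation with average ranks on ties; a
constant vector leaves ρ undefined (reported missing, never coerced).

## Functional profiles

Habitat pools are presence/absence unions of per-genome KO sets; Jaccard
similarity is |∩|/|∪| with the empty∅/empty case defined as 0 (flagged
with a warning) so similarity matrices stay total. FRR is
1 − distinct/total over KO-bearing genes only — genes without a KO are
outside the denominator, and a gene carries at most one KO in this data
model.

## Phylogenetic diversity

PD of a tip set is the branch-length sum of the minimal spanning subtree
rooted at the set's MRCA, excluding the edge above the MRCA (Faith PD,
unrooted-within-clade convention). The phrase "sum of all branch
distances in each subtree" is ambiguous about the stem; an
`include_stem` flag exposes the alternative. PD gain is
PD(reference ∪ added) − PD(reference), with percent gain relative to the
reference PD — i.e., growth over the pre-existing set. Zero-length edges
are allowed; a single-tip set has PD 0 (warned). Correctness is checked
against a brute-force oracle that sums edges on the union of all pairwise
tip paths.

## Taxa–habitat associations

A valid match is one (sample, taxon) row with relative abundance ≥ the
threshold (0.5 % by default; the comparison is inclusive). Habitat shares
are match fractions per habitat; peak abundance is the per-habitat
maximum. Habitat labels are taken as given — mapping environmental
ontologies onto soil/sediment/freshwater is upstream of this package.

## Statistical scaffold

The normality gate applies Shapiro-Wilk to pooled within-group residuals
at α = 0.05: parametric (one-way ANOVA, pairwise Welch t) on pass,
nonparametric (Kruskal-Wallis, pairwise Wilcoxon rank-sum with tie
correction) on fail; any group with n < 3 forces the nonparametric branch.
Pairwise families are Holm-adjusted — the conventional step-down default
for these pairwise procedures — and two-sided throughout. The permutation
t test uses the Welch (unequal-variance) statistic, permutes labels
without replacement, and estimates p with the add-one rule
(1 + #extreme)/(n_perm + 1), so p is never 0 with finite permutations;
when both groups are constant with differing means, the statistic is
treated as infinite (perfect separation) rather than 0. Compact letter
displays use insert-and-absorb: start from one all-group letter set,
split every set containing a significantly different pair, then absorb
subsets; the resulting letters encode the thresholded significance
relation exactly, including intransitive patterns (multi-letter groups).
Letters are assigned in descending-median group order for determinism.

## Synthetic-data generator

The generator's defaults define the study conditions. Four lineages,
oldest first, emulate the cross-ecosystem contrast: three large high-GC
lineages (relative sizes 3.2/2.8/2.4, genic GC 68.6/68.0/68.0 %,
intergenic GC ~5 points below genic, spacers 150–200 bp, sigma rates
9–10 per 1000 genes) and one reduced freshwater lineage (relative size
1.3, genic GC 63.15 %, intergenic GC 66 % — above genic, 12 bp mean
spacers, 3 sigma per 1000 genes, amino-acid usage shifted toward
Gly/Ala/Ser at the expense of Arg/Lys/His/Phe/Trp). Completeness and
contamination are drawn uniformly from [70, 95] % and [0, 5] %
(medians near 80 % and 1.6 %). Habitat-association profiles put the two
ancestral lineages at ~94.5 %/92.8 % soil, the expanded lineage at
71.4 % soil / 25 % sediment, and the reduced lineage at 98.7 %
freshwater. KO pools share a 400-KO core with 100/150/300
habitat-specific KOs for soil/sediment/freshwater, giving designed
Jaccard values of 0.615 (soil–sediment), 0.500 (soil–freshwater) and
0.471 (sediment–freshwater) — soil and sediment most alike. Expected FRR
is 0.05/0.08/0.30/0.10 per lineage, highest in the expanded lineage.
At desk scale, per-lineage gene counts scale from a 200-gene reference in
proportion to the size contrast; sizes are therefore scaled down
uniformly while every intensive quantity (GC, spacers, densities, rates,
composition) is at its study value.

**Codon usage construction.** Within each synonymous family, mass is
reweighted by a single multiplier x applied to G/C-ending codons and
renormalized per family, which preserves amino-acid marginals exactly;
x is solved (Brent's method) so that either the third-position GC equals
a requested level (`gen_codon_usage`) or the expected genic GC of a
gene — including its uniform terminal stop at the spec'd mean gene
length — equals the lineage target (`codon_usage_for_genic_gc`).
Requested values outside the attainable range (floored by
non-degenerate codons) raise rather than clip. In the study conditions
the genic GC target is the free parameter and GC3 is derived.

**Genomes.** One linear contig per genome by default (fragmentation is
orthogonal to every statistic here; an optional fragmenter splits at
spacer midpoints for robustness tests). Architecture alternates
intergenic tracts (i.i.d. bases at the intergenic GC target, lengths
Normal, floored at 0) and genes (codon-by-codon draws from the lineage
usage, closed by a uniform stop from {TAA, TAG, TGA}; stops never occur
internally). All genes sit on '+' by default; a flip option places genes
on '−' with probability 1/2, reverse-complementing the genomic segment
while keeping the emitted CDS on the coding strand. Proteins are in
silico translations (table 11). Gene count is set from the target genome
size; sigma-factor labels are Bernoulli at the lineage rate.

**KO tables.** Each genome receives its habitat's full pool as distinct
KOs, so pooled habitat sets reproduce the designed Jaccard matrix
exactly (set arithmetic, no sampling). Duplicates are injected at
d = round(u·f/(1−f)) to realize expected FRR f for u distinct KOs.
Habitat-specific sets must be pairwise disjoint and disjoint from the
core; overlap is an error because it would make the designed matrix
ill-defined.

**Trees.** Per-lineage pure-birth (Yule) subtrees — exponential waiting
times at rate × #lineages, uniform lineage choice — are grafted onto a
ladder backbone in lineage order with exponential stem lengths, so every
lineage is monophyletic with a positive stem; the root edge is 0.

**Abundance tables.** Habitat draws follow each taxon's profile
multinomially; abundances are LogNormal(log median, σ) with median 2 %
and σ = 1 by default, capped at 100 % — right-skewed with occasional
two-digit peaks, independent of the habitat draw.

**Determinism.** One root seed; per-genome streams derive from
SHA-256(root:genome_id) mod 2³¹, so adding a genome never perturbs the
others and runs are byte-identical across reruns.

**What the generator does not emulate.** Within-gene evolutionary
structure (codons are i.i.d.), indels, recombination, assembly error and
fragmentation noise, genes split across contigs, abundance–habitat
covariance, KO co-occurrence structure beyond the core/specific design,
and actual sequence incompleteness (completeness is metadata). Passing
recovery tests therefore certifies the estimators and their plumbing,
not robustness to real-data pathologies such as chimeric bins or biased
gene calling.

## Problem sizes and numerical choices

Recovery and contrast tests run on 4 lineages × 20 genomes with gene
counts scaled from a 200-gene reference — large enough that Monte-Carlo
error sits well inside the pre-registered tolerances (±0.01 on
fractions, ±10 % relative on lengths/rates, ±0.05 on FRR, ±0.02 atoms on
elemental means, exact on designed Jaccard). Rate recovery for rare
Bernoulli events (sigma factors) is tested on a dedicated
high-gene-count fixture where binomial error is ~3 % relative, because
at 200 genes the sampling noise of a 9/1000 rate exceeds any sensible
tolerance. The permutation-test calibration uses 500 null replicates of
n = 10 + 10 at 999 permutations; the funnel check uses three 20-genome
lineages at GC3 0.80/0.70/0.60. Root-finding tolerances are 1e-13 on the
reweighting multiplier; degenerate statistical inputs (constant groups,
empty sets, single tips) return missing values or raise, as documented
per function, and are never silently coerced.

## Limitations

- FRR counts at most one KO per gene; annotation pipelines that emit
  multiple database hits per gene need collapsing upstream.
- The letter display is deterministic but not guaranteed minimal in the
  number of letters (insert-and-absorb is exact, not minimal).
- PD conventions (stem inclusion, rooted vs MRCA-rooted) differ across
  the literature; both are exposed but the default is MRCA-rooted
  stem-exclusive.
- The pipeline's stats stage skips metrics that are degenerate within
  groups (e.g., designed-exact FRR at lineage level) rather than
  inventing a p-value.
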