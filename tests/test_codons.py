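"""Codon counting, GC by position, amino-acid composition and the
synonymous-family trend summary."""

from __future__ import annotations

import math

import numpy as np
import pytest

from limnoscope import synthetic
from limnoscope._genetic_code import CODON_INDEX, DEGENERATE_AAS
from limnoscope.codons import (
    aa_composition,
    codon_frequencies,
    gc_by_codon_position,
    gc_ending_share,
    strip_terminal_stop,
    synonymous_family_trend,
)


class TestStripTerminalStop:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGAAATAA", "ATGAAA"),
            ("ATGAAATAG", "ATGAAA"),
            ("ATGAAATGA", "ATGAAA"),
            ("ATGAAA", "ATGAAA"),
            ("ATGAAAT", "ATGAAAT"),  # last three "AAT": not a stop
            ("TA", "TA"),
        ],
    )
    def test_rule(self, cds, expected):
        assert strip_terminal_stop(cds) == expected


class TestCodonFrequencies:
    def test_single_codon_repeated(self):
        p = codon_frequencies(["ATGATG"])
        assert p.total_codons == 2
        assert p.freq[CODON_INDEX["ATG"]] == 1.0

    def test_two_codons_split(self):
        p = codon_frequencies(["ATGGAT"])
        assert p.freq[CODON_INDEX["ATG"]] == 0.5
        assert p.freq[CODON_INDEX["GAT"]] == 0.5

    def test_dropping_rules(self):
        """Ambiguous triplets and 1-2 nt remainders are dropped, counted."""
        p = codon_frequencies(["ATGGATNAA", "AT"])
        assert p.total_codons == 2
        assert p.freq[CODON_INDEX["ATG"]] == 0.5
        assert p.freq[CODON_INDEX["GAT"]] == 0.5
        assert p.n_dropped_ambiguous == 1
        assert p.n_dropped_remainder_nt == 2

    def test_empty_input_zero_profile(self):
        p = codon_frequencies([])
        assert p.total_codons == 0
        assert p.freq.sum() == 0.0

    def test_frequencies_reconstruct_counts(self, study_bundle):
        genome_id = study_bundle.genomes[0].genome_id
        cds = list(study_bundle.cds[genome_id].values())
        p = codon_frequencies(cds, genome_id=genome_id)
        assert p.freq.sum() == pytest.approx(1.0, abs=1e-9)
        counts = p.counts()
        assert counts.sum() == p.total_codons
        np.testing.assert_allclose(counts / p.total_codons, p.freq, atol=1e-12)


class TestGcByPosition:
    def test_all_gc(self):
        assert gc_by_codon_position(["GGG"]) == (100.0, 100.0, 100.0)

    def test_third_position_half(self):
        gc1, gc2, gc3 = gc_by_codon_position(["GATGAC"])
        assert (gc1, gc2, gc3) == (100.0, 0.0, 50.0)

    def test_all_at(self):
        assert gc_by_codon_position(["ATTATA"]) == (0.0, 0.0, 0.0)

    def test_genic_gc_equals_mean_of_positions(self, study_bundle):
        """With no dropped codons, genic GC equals the mean of GC1-3."""
        from limnoscope.genome_metrics import gc_content

        genome_id = study_bundle.genomes[0].genome_id
        cds = list(study_bundle.cds[genome_id].values())
        p = codon_frequencies(cds)
        assert p.n_dropped_ambiguous == 0 and p.n_dropped_remainder_nt == 0
        concat = "".join(cds)
        assert gc_content(concat) == pytest.approx(
            sum(p.gc_by_position) / 3, abs=1e-6
        )


class TestAaComposition:
    def test_single_residue(self):
        p = aa_composition(["GG"])
        assert p.pct[list("ACDEFGHIKLMNPQRSTVWY").index("G")] == 100.0

    def test_even_split(self):
        p = aa_composition(["GA"])
        idx = list("ACDEFGHIKLMNPQRSTVWY")
        assert p.pct[idx.index("G")] == 50.0
        assert p.pct[idx.index("A")] == 50.0

    def test_nonstandard_excluded(self):
        p = aa_composition(["GAX*"])
        assert p.n_residues == 2
        assert p.pct.sum() == pytest.approx(100.0)

    def test_empty_is_missing(self):
        with pytest.raises(ValueError):
            aa_composition(["XX"])

    def test_translation_matches_generator_marginals(
        self, study_bundle, study_truth
    ):
        """Pooled amino-acid composition of the emitted proteomes matches
        the marginals implied by the lineage codon usage (n >> 10,000)."""
        for name, spec in study_truth.items():
            proteins = [
                seq
                for g in study_bundle.genomes
                if g.lineage == name
                for seq in study_bundle.proteins[g.genome_id].values()
            ]
            profile = aa_composition(proteins)
            np.testing.assert_allclose(
                profile.pct / 100, spec.aa_usage, atol=0.01
            )


class TestSynonymousFamilyTrend:
    @staticmethod
    def _profiles_at_gc3(levels, n_genomes=8, n_genes=40, seed=0):
        base = np.zeros(64)
        from limnoscope._genetic_code import AA_TO_CODONS

        for codons in AA_TO_CODONS.values():
            for c in codons:
                base[CODON_INDEX[c]] = 1.0
        base /= base.sum()
        groups = []
        for k, level in enumerate(levels):
            usage = synthetic.gen_codon_usage(level, base)
            spec = synthetic.LineageSpec(
                name=f"L{k}",
                n_genomes=n_genomes,
                genome_size_bp=(n_genes * 312.0, 500),
                gene_length_bp=(300.0, 30.0),
                intergenic_length_bp=(12.0, 4.0),
                codon_usage=usage,
                intergenic_gc_target=0.5,
                habitat="soil",
            )
            profiles = []
            for i in range(n_genomes):
                rng = np.random.default_rng(
                    synthetic.derive_seed(seed, f"L{k}_g{i}")
                )
                _, cds, _ = synthetic.gen_genome(spec, rng)
                profiles.append(codon_frequencies(list(cds.values())))
            groups.append((f"L{k}", profiles))
        return groups

    def test_identical_groups_zero_trend(self):
        groups = self._profiles_at_gc3([0.7])
        df = synonymous_family_trend([groups[0], groups[0]])
        assert (df["trend_sign"] == 0).all()

    def test_two_group_sign_is_difference_sign(self):
        groups = self._profiles_at_gc3([0.8, 0.6])
        df = synonymous_family_trend(groups)
        for _, row in df.iterrows():
            lo = row["mean_gc_share[L1]"]
            hi = row["mean_gc_share[L0]"]
            assert row["trend_sign"] == int(np.sign(lo - hi))

    def test_gradient_yields_funnel(self):
        """gc3 0.8 -> 0.7 -> 0.6: nearly all 18 degenerate families lose
        GC-ending share monotonically."""
        groups = self._profiles_at_gc3([0.8, 0.7, 0.6], n_genomes=12)
        df = synonymous_family_trend(groups)
        assert df.attrs["n_families"] == 18
        assert df.attrs["n_decreasing"] >= 16

    def test_single_group_rejected(self):
        groups = self._profiles_at_gc3([0.7])
        with pytest.raises(ValueError):
            synonymous_family_trend(groups)

    def test_gc_share_nan_for_absent_family(self):
        p = codon_frequencies(["ATGATG"])  # only Met observed
        assert math.isnan(gc_ending_share(p, "D"))
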