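"""Generator correctness: the planted truth must be independently verifiable."""

import numpy as np
import pytest
from Bio.Seq import Seq

from phagekit import synthgen as sg
from phagekit.seqio import reverse_complement


class TestGenomeSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(length=500, gc=0.4, n_cds=0),
        dict(length=2000, gc=0.0, n_cds=0),
        dict(length=2000, gc=1.2, n_cds=0),
        dict(length=2000, gc=0.4, n_cds=0, dtr_length=1500),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(sg.SpecError):
            sg.GenomeSpec(seed=0, **kwargs)

    def test_capacity_error_when_cds_do_not_fit(self):
        spec = sg.GenomeSpec(length=1000, gc=0.4, n_cds=10, seed=0)
        with pytest.raises(sg.CapacityError):
            sg.make_genome(spec)


class TestMakeGenome:
    def test_length_gc_cds_at_study_scale(self, ja1_like):
        genome, truth = ja1_like
        assert len(genome) == 69_278
        gc = 100 * (genome.sequence.count("G") + genome.sequence.count("C")) / len(genome)
        assert 34.1 <= gc <= 35.1
        assert len(genome.cds) == 79
        assert truth.dtr == (69_278 - 1_974, 69_278)

    def test_trivial_featureless_genome(self):
        spec = sg.GenomeSpec(length=1000, gc=0.5, n_cds=0, dtr_length=0, seed=7)
        genome, truth = sg.make_genome(spec)
        assert len(genome) == 1000 and genome.features == []
        assert truth.dtr is None

    def test_determinism(self):
        spec = sg.GenomeSpec(length=5000, gc=0.45, n_cds=3, dtr_length=200, seed=42)
        g1, _ = sg.make_genome(spec)
        g2, _ = sg.make_genome(spec)
        assert g1.sequence == g2.sequence
        assert g1.features == g2.features

    def test_cds_are_clean_orfs(self, small_genome):
        genome, _ = small_genome
        for f in genome.cds:
            nt = genome.feature_sequence(f)
            assert len(nt) % 3 == 0 and len(nt) >= 300
            assert nt[:3] == "ATG"
            prot = str(Seq(nt).translate(table=11))
            assert prot.endswith("*") and "*" not in prot[:-1]

    def test_planted_homopolymer_tracts_are_maximal(self, ja1_like):
        genome, truth = ja1_like
        lengths = sorted(t[2] - t[1] for t in truth.homopolymer_tracts)
        assert lengths == [7, 8, 12]
        for base, s, e in truth.homopolymer_tracts:
            assert set(genome.sequence[s:e]) == {base}
            assert genome.sequence[s - 1] != base
            assert genome.sequence[e] != base


class TestRedundantForm:
    def test_study_scale_arithmetic(self, ja1_like):
        genome, _ = ja1_like
        assert len(sg.make_redundant_form(genome, 1_974)) == 71_252

    def test_zero_dtr_is_identity(self):
        assert sg.make_redundant_form("ACGTACGT", 0) == "ACGTACGT"

    def test_tiny_example_by_construction(self):
        assert sg.make_redundant_form("ACGTAC", 2) == "ACACGTAC"

    def test_length_difference_always_dtr(self, small_genome):
        genome, _ = small_genome
        for d in (0, 1, 57, 500):
            assert len(sg.make_redundant_form(genome, d)) - len(genome) == d

    def test_too_long_dtr_rejected(self):
        with pytest.raises(ValueError):
            sg.make_redundant_form("ACGT", 5)


class TestDivergePair:
    def test_empty_spec_gives_identical_pair(self, small_genome):
        genome, truth_a = small_genome
        b, truth = sg.diverge_pair(genome, sg.DivergenceSpec(0, 0, 0, 0, seed=1),
                                   truth_a)
        assert b.sequence == genome.sequence
        assert truth.substitutions == [] and truth.indels == []

    def test_requested_event_counts_planted(self, small_genome):
        genome, truth_a = small_genome
        spec = sg.DivergenceSpec(10, 15, 8, 2, seed=5)
        b, truth = sg.diverge_pair(genome, spec, truth_a)
        counts = truth.counts()
        assert counts["intergenic"] == 10
        assert counts["synonymous"] == 15
        assert counts["nonsynonymous"] == 8
        assert counts["indels"] == 2
        diffs = sum(x != y for x, y in zip(genome.sequence, b.sequence))
        assert diffs >= 33  # indels shift the tail, so >= the substitutions

    def test_planted_classes_verify_by_retranslation(self, small_genome):
        """Independent oracle: re-translate every planted codon in both genomes
        through Biopython's table 11 and check the intended class."""
        genome, truth_a = small_genome
        spec = sg.DivergenceSpec(5, 12, 9, 0, seed=9)
        b, truth = sg.diverge_pair(genome, spec, truth_a)
        cds_by_tag = {f.locus_tag: f for f in genome.cds}
        for sub in truth.substitutions:
            assert genome.sequence[sub.pos_a] == sub.ref
            assert b.sequence[sub.pos_a] == sub.alt  # no indels: coords match
            if sub.klass == "intergenic":
                assert all(not f.contains0(sub.pos_a) for f in genome.cds)
                continue
            f = cds_by_tag[sub.locus_tag]
            s, e = f.slice0()
            nt_a, nt_b = genome.sequence[s:e], b.sequence[s:e]
            if f.strand == "-":
                nt_a, nt_b = reverse_complement(nt_a), reverse_complement(nt_b)
            # compare only the codon holding this substitution: a CDS may
            # carry several independent plantings of different classes
            coding_pos = (sub.pos_a - s) if f.strand == "+" else (e - 1 - sub.pos_a)
            ci = coding_pos // 3
            aa_a = str(Seq(nt_a[3 * ci:3 * ci + 3]).translate(table=11))
            aa_b = str(Seq(nt_b[3 * ci:3 * ci + 3]).translate(table=11))
            assert nt_a[3 * ci:3 * ci + 3] != nt_b[3 * ci:3 * ci + 3]
            if sub.klass == "synonymous":
                assert aa_a == aa_b
            else:
                assert aa_a != aa_b

    def test_coding_requests_need_annotation(self):
        spec = sg.GenomeSpec(length=2000, gc=0.4, n_cds=0, seed=0)
        genome, _ = sg.make_genome(spec)
        with pytest.raises(sg.CapacityError):
            sg.diverge_pair(genome, sg.DivergenceSpec(0, 5, 0, 0, seed=1))

    def test_determinism(self, small_genome):
        genome, truth_a = small_genome
        spec = sg.DivergenceSpec(5, 5, 5, 1, seed=3)
        b1, t1 = sg.diverge_pair(genome, spec, truth_a)
        b2, t2 = sg.diverge_pair(genome, spec, truth_a)
        assert b1.sequence == b2.sequence
        assert t1.substitutions == t2.substitutions

    def test_cds_deletion_removes_annotation(self, small_genome):
        genome, truth_a = small_genome
        spec = sg.DivergenceSpec(0, 0, 0, 1, seed=2, cds_deletion=True)
        b, truth = sg.diverge_pair(genome, spec, truth_a)
        assert len(b.cds) == len(genome.cds) - 1
        (ev,) = truth.indels
        assert ev.kind == "del" and ev.length >= 300


class TestSimulateReads:
    def test_read_count_and_total_bases(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 10_000))
        reads = sg.simulate_reads(seq, coverage=30, read_length=100, seed=3)
        total = sum(len(r.sequence) for r in reads)
        assert 285_000 <= total <= 315_000

    def test_error_free_reads_are_exact_substrings(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 5_000))
        for r in sg.simulate_reads(seq, coverage=5, read_length=80, seed=4):
            assert seq[r.start:r.start + 80] == r.sequence

    def test_error_rate_produces_mismatches(self):
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), 5_000))
        reads = sg.simulate_reads(seq, 10, 100, error_rate=0.02, seed=5)
        mismatches = sum(
            sum(a != b for a, b in zip(r.sequence, seq[r.start:r.start + 100]))
            for r in reads)
        total = 100 * len(reads)
        assert 0.01 < mismatches / total < 0.04

    def test_zero_expected_reads_warns(self):
        with pytest.warns(UserWarning):
            reads = sg.simulate_reads("ACGT" * 300, coverage=0.01,
                                      read_length=1000, seed=0)
        assert reads == []

    def test_read_longer_than_template_rejected(self):
        with pytest.raises(ValueError):
            sg.simulate_reads("ACGT" * 10, 5, 100, seed=0)
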