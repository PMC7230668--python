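"""Ground-truth generators: determinism and statistical contracts."""

import math

import numpy as np
import pytest

from krillsurvey.seq_io import SeqRecord
from krillsurvey.synthetic_data import (
    SimGenomeSpec,
    SimReadSpec,
    back_translate,
    make_toy_mito,
    plant_peptides,
    plant_ssrs,
    random_amp_reference,
    simulate_diploid_genome,
    simulate_reads,
)

from conftest import random_dna

_COMP = str.maketrans("ACGT", "TGCA")


class TestDiploidGenome:
    def test_zero_heterozygosity_gives_identical_haplotypes(self):
        a, b, variants = simulate_diploid_genome(SimGenomeSpec(size=5000, seed=1))
        assert a.seq == b.seq and variants == []

    def test_variant_count_within_binomial_ci(self):
        spec = SimGenomeSpec(size=10_000, heterozygosity=0.01, seed=1)
        _, _, variants = simulate_diploid_genome(spec)
        mean = 100
        sigma = math.sqrt(10_000 * 0.01 * 0.99)
        assert abs(len(variants) - mean) <= 3 * sigma
        a, b, _ = simulate_diploid_genome(spec)
        diffs = sum(1 for x, y in zip(a.seq, b.seq) if x != y)
        assert diffs == len(variants)

    def test_gc_content_close_to_spec(self):
        spec = SimGenomeSpec(size=100_000, gc=0.42, seed=2)
        a, _, _ = simulate_diploid_genome(spec)
        gc = (a.seq.count("G") + a.seq.count("C")) / len(a.seq)
        assert abs(gc - 0.42) < 0.02

    def test_same_seed_same_output(self):
        spec = SimGenomeSpec(size=2000, heterozygosity=0.02, seed=7)
        assert simulate_diploid_genome(spec)[0].seq == simulate_diploid_genome(spec)[0].seq

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SimGenomeSpec(size=10)
        with pytest.raises(ValueError):
            SimGenomeSpec(heterozygosity=0.5)
        with pytest.raises(ValueError):
            SimGenomeSpec(gc=0.0)


class TestReads:
    def test_error_free_reads_are_substrings_of_a_haplotype(self):
        spec = SimGenomeSpec(size=50_000, heterozygosity=0.01, seed=3)
        a, b, _ = simulate_diploid_genome(spec)
        reads = simulate_reads(a, b, SimReadSpec(100, 2.0, 0.0, seed=4))
        hay = {
            a.seq,
            b.seq,
            a.seq.translate(_COMP)[::-1],
            b.seq.translate(_COMP)[::-1],
        }
        for read in reads[:200]:
            assert any(read.seq in h for h in hay)

    def test_total_bases_close_to_depth_times_size(self):
        a, _, _ = simulate_diploid_genome(SimGenomeSpec(size=50_000, seed=5))
        reads = simulate_reads(a, None, SimReadSpec(100, 30.0, 0.0, seed=6))
        total = sum(len(r) for r in reads)
        assert abs(total - 30 * 50_000) / (30 * 50_000) < 0.01

    def test_fixed_seed_is_deterministic(self):
        a, _, _ = simulate_diploid_genome(SimGenomeSpec(size=5000, seed=5))
        spec = SimReadSpec(50, 2.0, 0.01, seed=9)
        r1 = simulate_reads(a, None, spec)
        r2 = simulate_reads(a, None, spec)
        assert [(x.seq, x.quals) for x in r1] == [(x.seq, x.quals) for x in r2]

    def test_read_longer_than_genome_rejected(self):
        a, _, _ = simulate_diploid_genome(SimGenomeSpec(size=1000, seed=5))
        with pytest.raises(ValueError):
            simulate_reads(a, None, SimReadSpec(2000, 1.0, 0.0, seed=0))

    def test_circular_reads_span_origin(self):
        a, _, _ = simulate_diploid_genome(SimGenomeSpec(size=1000, seed=8))
        reads = simulate_reads(a, None, SimReadSpec(100, 20.0, 0.0, seed=8),
                               circular=True)
        doubled = a.seq + a.seq
        doubled_rc = doubled.translate(_COMP)[::-1]
        assert all(r.seq in doubled or r.seq in doubled_rc for r in reads)
        starts = [int(r.description.split("start=")[1].split()[0]) for r in reads]
        assert max(starts) > len(a.seq) - 100  # some reads wrap


class TestPlantSSRs:
    def test_truth_uses_scanner_coordinates(self, rng):
        bg = SeqRecord(id="bg", seq=random_dna(rng, 1000))
        _, truth = plant_ssrs(bg, [("AC", 6, 100)], seed=0)
        (t,) = truth
        assert (t.motif, t.repeats, t.start, t.end) == ("AC", 6, 100, 111)

    def test_two_tracts_two_records(self, rng):
        bg = SeqRecord(id="bg", seq=random_dna(rng, 1000))
        _, truth = plant_ssrs(bg, [("ATG", 5, 50), ("TA", 7, 500)], seed=0)
        assert len(truth) == 2

    def test_overlapping_tracts_raise(self, rng):
        bg = SeqRecord(id="bg", seq=random_dna(rng, 1000))
        with pytest.raises(ValueError, match="overlap"):
            plant_ssrs(bg, [("AC", 6, 100), ("ATG", 5, 105)], seed=0)


class TestPlantPeptides:
    def test_identity_one_plants_exact_copy(self):
        refs = random_amp_reference(3, seed=1)
        proteins, _, truth = plant_peptides(10, refs, ["VSV"], identity=1.0, seed=2)
        for pid, amp_id, start, end, realised in truth.amps:
            prot = next(p for p in proteins if p.id == pid)
            amp_seq = dict((e[0], e[2]) for e in refs.entries)[amp_id]
            assert prot.seq[start - 1 : end] == amp_seq
            assert realised == 1.0

    def test_ahtp_truth_rows_match_protein_text(self):
        refs = random_amp_reference(2, seed=3)
        proteins, _, truth = plant_peptides(8, refs, ["VSV", "GLP"], seed=4)
        by_id = {p.id: p.seq for p in proteins}
        assert truth.ahtps, "at least the planted occurrences must be recorded"
        for pid, pep, start, end in truth.ahtps:
            assert by_id[pid][start - 1 : end] == pep
            assert end - start + 1 == len(pep)

    def test_contigs_six_frame_translate_to_planted_proteins(self):
        from krillsurvey.peptide_screen import six_frame_segments

        refs = random_amp_reference(2, seed=5)
        proteins, contigs, _ = plant_peptides(5, refs, ["LKP"], seed=6)
        for prot, contig in zip(proteins, contigs):
            segments = [seg for _, _, seg in six_frame_segments(contig.seq)]
            assert any(prot.seq in seg for seg in segments)

    def test_identity_outside_range_rejected(self):
        refs = random_amp_reference(1, seed=0)
        with pytest.raises(ValueError):
            plant_peptides(5, refs, [], identity=0.4, seed=0)


class TestBackTranslate:
    def test_round_trip_standard_code(self, rng):
        from Bio.Seq import Seq

        prot = "MKVLDEWRTS"
        nt = back_translate(prot, np.random.default_rng(0), table=1)
        assert str(Seq(nt).translate(table=1)) == prot

    def test_round_trip_mito_code(self):
        from Bio.Seq import Seq

        prot = "MSWK"
        nt = back_translate(prot, np.random.default_rng(0), table=5)
        assert str(Seq(nt).translate(table=5)) == prot


class TestToyMito:
    def test_genes_translate_correctly_under_mito_code(self):
        from Bio.Seq import Seq

        ref = make_toy_mito(seed=1)
        assert len(ref.genes) == 4 and ref.circular
        for gene in ref.genes:
            (s, e, strand) = gene.spans[0]
            cds = ref.seq[s:e]
            assert strand == 1
            aa = str(Seq(cds).translate(table=5))
            assert aa == gene.translation + "*"

    def test_deterministic(self):
        assert make_toy_mito(seed=2).seq == make_toy_mito(seed=2).seq
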