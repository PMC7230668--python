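"""ORF extraction, the local aligner vs a DP oracle, and peptide screens."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from krillsurvey.peptide_screen import (
    AMPReference,
    find_orfs,
    local_align,
    map_ahtps,
    screen_amps,
    six_frame_segments,
)
from krillsurvey.seq_io import SeqRecord
from krillsurvey.synthetic_data import plant_peptides, random_amp_reference

from conftest import random_protein

_B62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(query, target, gap_open=11, gap_extend=1):
    """Quadratic-space affine-gap Smith-Waterman score, straight from the
    recurrences (gap of length g costs gap_open + gap_extend*(g-1))."""
    n, m = len(query), len(target)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + _B62[query[i - 1]][target[j - 1]]
            H[i][j] = max(0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


class TestOrfs:
    def test_minimal_orf_with_stop(self):
        orfs = find_orfs(SeqRecord(id="t", seq="ATGAAATAA"), min_aa=1)
        plus = [o for o in orfs if o.frame == 1]
        assert any(
            o.protein == "MK" and (o.start, o.end) == (1, 9) and o.has_stop
            for o in plus
        )

    def test_stop_riddled_sequence_yields_nothing(self):
        # every frame is broken by stops or too short once min_aa applies
        assert find_orfs(SeqRecord(id="t", seq="TAATAATAA"), min_aa=4) == []

    def test_min_length_filter(self):
        orfs = find_orfs(SeqRecord(id="t", seq="ATGAAATAA"), min_aa=100)
        assert orfs == []

    def test_longest_flagged_once(self):
        seq = "ATG" + "AAA" * 30 + "TAA"
        orfs = find_orfs(SeqRecord(id="t", seq=seq), min_aa=1)
        assert sum(o.longest for o in orfs) == 1
        assert max(orfs, key=lambda o: len(o.protein)).longest

    def test_planted_protein_recovered_exactly(self):
        refs = random_amp_reference(2, seed=1)
        proteins, contigs, _ = plant_peptides(4, refs, [], seed=2)
        for prot, contig in zip(proteins, contigs):
            orfs = find_orfs(contig, min_aa=10)
            assert any(o.protein == prot.seq for o in orfs)

    def test_six_frame_segments_cover_both_strands(self):
        segs = six_frame_segments("ATGAAATTTGGG")
        frames = {f for f, _, _ in segs}
        assert frames == {1, 2, 3, -1, -2, -3}


class TestLocalAlign:
    def test_identity_alignment_scores_by_matrix(self):
        hit = local_align("MKV", "MKV")
        assert hit.raw_score == 14  # 5 + 5 + 4 under BLOSUM62
        assert hit.query_align_ratio == 1.0
        assert hit.identity == 1.0

    def test_no_positive_alignment_returns_none(self):
        assert local_align("AAAA", "CCCC") is None

    def test_score_symmetric_under_swap(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(5, 25)))
            b = random_protein(rng, int(rng.integers(5, 25)))
            ha, hb = local_align(a, b), local_align(b, a)
            assert (ha is None) == (hb is None)
            if ha is not None:
                assert ha.raw_score == hb.raw_score

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            q = random_protein(rng, int(rng.integers(3, 31)))
            t = random_protein(rng, int(rng.integers(3, 31)))
            expected = sw_oracle(q, t)
            hit = local_align(q, t)
            got = 0 if hit is None else hit.raw_score
            assert got == expected

    def test_unknown_residue_scored_as_x(self):
        hit = local_align("MKU", "MKX")  # U outside BLOSUM62 -> X column
        assert hit is not None and hit.raw_score == sw_oracle("MKX", "MKX")

    def test_evalue_decreases_with_score(self):
        short = local_align("MKV", "MKV")
        long_ = local_align("MKVWYE", "MKVWYE")
        assert long_.raw_score > short.raw_score
        assert long_.evalue < short.evalue

    def test_spans_address_the_aligned_residues(self):
        hit = local_align("KVW", "AAAKVWAAA")
        assert hit.query_span == (1, 3)
        assert hit.target_span == (4, 6)


class TestScreenAmps:
    def test_planted_homologs_recovered_and_decoys_clean(self):
        refs = random_amp_reference(8, seed=10)
        proteins, _, truth = plant_peptides(60, refs, [], identity=0.9, seed=11)
        hits, families = screen_amps(refs, proteins)
        planted = {(t[1], t[0]) for t in truth.amps}
        got = {(h.query_id, h.target_id) for h in hits}
        assert planted <= got
        carriers = {t[0] for t in truth.amps}
        assert {h.target_id for h in hits} <= carriers  # no decoy hits
        assert sum(families.values()) == len(hits)

    def test_truncated_homolog_rejected_by_ratio(self, rng):
        refs = AMPReference([("amp1", "fam", random_protein(rng, 40))])
        # only 40% of the query is present in the target: the hit passes
        # the E-value filter but not the align-ratio filter
        target = SeqRecord(id="p1", seq=refs.entries[0][2][:16])
        unfiltered, _ = screen_amps(refs, [target], min_ratio=0.0)
        assert len(unfiltered) == 1
        assert unfiltered[0].query_align_ratio == pytest.approx(0.4)
        hits, _ = screen_amps(refs, [target])
        assert hits == []

    def test_identical_query_target_has_ratio_one(self):
        seq = "MKWVQRLLDEFGHIKWWQER"
        hits, _ = screen_amps(
            AMPReference([("a", "f", seq)]), [SeqRecord(id="t", seq=seq)]
        )
        assert len(hits) == 1
        assert hits[0].query_align_ratio == 1.0

    def test_filters_are_monotone(self):
        refs = random_amp_reference(4, seed=12)
        proteins, _, _ = plant_peptides(20, refs, [], identity=0.85, seed=13)
        loose, _ = screen_amps(refs, proteins, evalue_max=math.inf, min_ratio=0.0)
        tight, _ = screen_amps(refs, proteins, evalue_max=1e-5, min_ratio=0.5)
        loose_keys = {(h.query_id, h.target_id) for h in loose}
        tight_keys = {(h.query_id, h.target_id) for h in tight}
        assert tight_keys <= loose_keys

    def test_nucleotide_targets_are_translated(self):
        refs = random_amp_reference(3, seed=14)
        proteins, contigs, truth = plant_peptides(8, refs, [], identity=1.0, seed=15)
        hits, _ = screen_amps(refs, contigs, target_type="nucleotide")
        planted = {t[1] for t in truth.amps}
        assert planted <= {h.query_id for h in hits}
        assert all(h.frame is not None for h in hits)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            screen_amps(AMPReference([]), [SeqRecord(id="p", seq="MKV")])


class TestMapAhtps:
    def test_two_peptides_two_hits(self):
        hits, per_prot, per_pep = map_ahtps(
            ["VSV", "GLP"], [SeqRecord(id="p", seq="AVSVGLP")]
        )
        assert {(h.peptide, h.start, h.end) for h in hits} == {
            ("VSV", 2, 4),
            ("GLP", 5, 7),
        }
        assert per_prot == {"p": 2}

    def test_overlapping_occurrences_all_counted(self):
        hits, per_prot, per_pep = map_ahtps(["AA"], [SeqRecord(id="p", seq="AAAA")])
        assert [(h.start, h.end) for h in hits] == [(1, 2), (2, 3), (3, 4)]
        assert per_pep["AA"] == 3

    def test_peptide_length_validated(self):
        with pytest.raises(ValueError):
            map_ahtps(["A"], [])
        with pytest.raises(ValueError):
            map_ahtps(["A" * 11], [])

    def test_matches_naive_oracle_on_random_draws(self, rng):
        for _ in range(300):
            prot = random_protein(rng, int(rng.integers(10, 80)))
            peps = [
                random_protein(rng, int(rng.integers(2, 5)))
                for _ in range(int(rng.integers(1, 5)))
            ]
            peps = list(dict.fromkeys(peps))
            hits, _, _ = map_ahtps(peps, [SeqRecord(id="p", seq=prot)])
            expected = {
                (pep, i + 1, i + len(pep))
                for pep in peps
                for i in range(len(prot) - len(pep) + 1)
                if prot[i : i + len(pep)] == pep
            }
            assert {(h.peptide, h.start, h.end) for h in hits} == expected

    def test_planted_fixture_equals_truth(self):
        refs = random_amp_reference(2, seed=20)
        peps = ["VSV", "GLP", "LRP", "GGY"]
        proteins, _, truth = plant_peptides(15, refs, peps, seed=21)
        hits, _, _ = map_ahtps(peps, proteins)
        got = {(h.protein_id, h.peptide, h.start, h.end) for h in hits}
        assert got == set(truth.ahtps)
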