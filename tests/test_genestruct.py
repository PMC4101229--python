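"""Coverage segmentation, intron candidacy, HSP splitting, complete introns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captureseq.genestruct import (
    HSP,
    CoverageProfile,
    align_contig_to_targets,
    call_segments,
    candidate_intron_contigs,
    classify_complete_introns,
    coverage_profile,
    intron_stats,
)
from captureseq.mapping import ReadAlignment
from tests.conftest import random_dna


def rna_aln(contig_id: str, start: int, length: int, read_id: str = "r") -> ReadAlignment:
    return ReadAlignment(
        read_id=read_id, ref_id=contig_id, ref_start=start, strand="+",
        operations=[("M", length)], identity=1.0, aligned_fraction=1.0,
        score=length, query_start=0, query_end=length,
        oriented_sequence="A" * length,
    )


def profile_from_depth(depth, contig_id="c") -> CoverageProfile:
    return CoverageProfile(contig_id, np.asarray(depth, dtype=np.int32))


class TestCoverageProfile:
    def test_no_alignments_zero_covered(self):
        p = coverage_profile([], "c", 100)
        assert p.covered_length == 0 and p.covered_fraction == 0.0

    def test_single_read_half_coverage(self):
        p = coverage_profile([rna_aln("c", 0, 50)], "c", 100)
        assert p.covered_length == 50 and p.covered_fraction == 0.5

    def test_overlap_depth_two(self):
        p = coverage_profile(
            [rna_aln("c", 0, 30, "a"), rna_aln("c", 20, 30, "b")], "c", 60
        )
        assert (p.depth[20:30] == 2).all()
        assert (p.depth[:20] == 1).all() and (p.depth[30:50] == 1).all()


class TestCallSegments:
    def test_internal_gap_becomes_intron(self):
        depth = [1] * 100 + [0] * 100 + [1] * 100
        segs = call_segments(profile_from_depth(depth))
        assert segs == [("exon", 0, 100), ("intron", 100, 200), ("exon", 200, 300)]

    def test_short_gap_absorbed(self):
        depth = [1] * 100 + [0] * 50 + [1] * 100
        segs = call_segments(profile_from_depth(depth), min_gap=100)
        assert segs == [("exon", 0, 250)]

    def test_fully_covered_single_exon(self):
        segs = call_segments(profile_from_depth([2] * 300))
        assert segs == [("exon", 0, 300)]

    def test_end_gaps_are_flanks_not_introns(self):
        depth = [0] * 150 + [1] * 100 + [0] * 150
        segs = call_segments(profile_from_depth(depth))
        assert segs == [
            ("unresolved_flank", 0, 150),
            ("exon", 150, 250),
            ("unresolved_flank", 250, 400),
        ]

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=400))
    @settings(max_examples=80, deadline=None)
    def test_segments_partition_contig(self, depth):
        segs = call_segments(profile_from_depth(depth))
        assert segs[0][1] == 0 and segs[-1][2] == len(depth)
        for (k1, s1, e1), (k2, s2, e2) in zip(segs, segs[1:]):
            assert e1 == s2
        assert sum(e - s for _, s, e in segs) == len(depth)


class TestCandidates:
    @pytest.mark.parametrize(
        "length,covered,expected",
        [(700, 400, True), (700, 500, False), (250, 0, True)],
    )
    def test_divergence_rule(self, length, covered, expected):
        depth = [1] * covered + [0] * (length - covered)
        profiles = {"c": profile_from_depth(depth)}
        ids = candidate_intron_contigs(profiles, min_divergence=250)
        assert (ids == ["c"]) is expected


class TestHSPs:
    def test_intron_splits_alignment_into_two_hsps(self, rng):
        exon1, exon2 = random_dna(rng, 200), random_dna(rng, 200)
        intron = random_dna(rng, 300)
        transcript = exon1 + exon2
        contig = exon1 + intron + exon2
        hsps = align_contig_to_targets(contig, {"t": transcript})
        assert len(hsps) == 2
        (h1, h2) = hsps
        assert (h1.query_start, h1.query_end) == (0, 200)
        assert (h2.query_start, h2.query_end) == (500, 700)
        assert (h1.subject_start, h1.subject_end) == (0, 200)
        assert (h2.subject_start, h2.subject_end) == (200, 400)

    def test_no_similarity_no_hsps(self, rng):
        assert align_contig_to_targets(
            random_dna(rng, 300), {"t": random_dna(rng, 300)}
        ) == []

    def test_fully_exonic_contig_one_hsp(self, rng):
        transcript = random_dna(rng, 600)
        hsps = align_contig_to_targets(transcript[100:500], {"t": transcript})
        assert len(hsps) == 1
        assert hsps[0].query_start == 0 and hsps[0].query_end == 400

    def test_reverse_strand_contig(self, rng):
        from captureseq.align import revcomp

        exon1, exon2 = random_dna(rng, 200), random_dna(rng, 200)
        intron = random_dna(rng, 300)
        contig = revcomp(exon1 + intron + exon2)
        hsps = align_contig_to_targets(contig, {"t": exon1 + exon2})
        assert len(hsps) == 2 and all(h.strand == "-" for h in hsps)
        calls = classify_complete_introns("c", contig, hsps)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (200, 500)
        assert calls[0].complete


class TestCompleteIntrons:
    @staticmethod
    def hsp(qs, qe, ss, se, tid="t", strand="+"):
        return HSP(tid, qs, qe, ss, se, qe - qs, 1.0, strand,
                   operations=[("M", qe - qs)])

    def test_subject_adjacent_pair_yields_intron(self):
        hsps = [self.hsp(0, 200, 0, 200), self.hsp(500, 700, 200, 400)]
        calls = classify_complete_introns("c", "A" * 700, hsps)
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end, call.length) == (200, 500, 300)
        assert call.complete  # bracketed by exon-anchored HSPs on both sides

    def test_interior_intron_is_complete(self):
        hsps = [self.hsp(10, 210, 0, 200), self.hsp(510, 690, 200, 380)]
        calls = classify_complete_introns("c", "A" * 700, hsps)
        assert calls[0].complete

    def test_single_hsp_no_intron(self):
        assert classify_complete_introns("c", "A" * 500, [self.hsp(0, 200, 0, 200)]) == []

    def test_subject_gap_beyond_tolerance_rejected(self):
        hsps = [self.hsp(0, 200, 0, 200), self.hsp(500, 700, 230, 430)]
        assert classify_complete_introns("c", "A" * 700, hsps) == []

    def test_planted_intron_recovery(self, rng):
        """20 synthetic exon-intron-exon contigs: >= 18 introns recovered with
        boundaries within +/- 5 bp."""
        recovered = 0
        for i in range(20):
            e1 = random_dna(rng, int(rng.integers(150, 400)))
            e2 = random_dna(rng, int(rng.integers(150, 400)))
            intron_len = int(rng.integers(150, 800))
            intron = random_dna(rng, intron_len)
            flank = random_dna(rng, 50)
            contig = flank + e1 + intron + e2 + flank
            transcript = e1 + e2
            hsps = align_contig_to_targets(contig, {f"t{i}": transcript})
            calls = [
                c for c in classify_complete_introns(f"c{i}", contig, hsps)
                if c.complete
            ]
            true_start = 50 + len(e1)
            true_end = true_start + intron_len
            for c in calls:
                if abs(c.start - true_start) <= 5 and abs(c.end - true_end) <= 5:
                    recovered += 1
                    break
        assert recovered >= 18

    def test_stats_summary(self):
        hsps = [self.hsp(10, 210, 0, 200), self.hsp(510, 690, 200, 380)]
        calls = classify_complete_introns("c", "A" * 700, hsps)
        st = intron_stats(calls)
        assert st.n_introns == 1 and st.total_length == 300
        assert st.mean_length == 300 and st.min_length == st.max_length == 300
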