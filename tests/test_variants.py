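"""Pileup construction, SNP thresholds, Ts/Tv classing, set intersection."""

import numpy as np
import pytest

from captureseq.genestruct import HSP
from captureseq.mapping import ReadAlignment
from captureseq.variants import (
    SNPCall,
    build_pileup,
    call_snps,
    classify_ts_tv,
    intersect_snp_sets,
    liftover_position,
    snp_frequency,
)
from tests.conftest import random_dna


def aligned(contig: str, start: int, seq: str, read_id: str = "r",
            strand: str = "+") -> ReadAlignment:
    return ReadAlignment(
        read_id=read_id, ref_id=contig, ref_start=start, strand=strand,
        operations=[("M", len(seq))], identity=1.0, aligned_fraction=1.0,
        score=len(seq), query_start=0, query_end=len(seq),
        oriented_sequence=seq,
    )


def snp(contig, pos, ref, alt, source="genomic") -> SNPCall:
    return SNPCall(contig, pos, ref, alt, 20, 0.5, classify_ts_tv(ref, alt),
                   source=source)


class TestBuildPileup:
    def test_identical_locus_reads_counted_once(self):
        ref = "ACGTACGTAC"
        alns = [aligned("c", 0, ref, f"r{i}") for i in range(10)]
        counts = build_pileup(alns, "c", ref)
        assert counts.sum() == len(ref)  # a single read's worth

    def test_single_read_counts_reference_bases(self):
        ref = "ACGTACGT"
        counts = build_pileup([aligned("c", 0, ref)], "c", ref)
        for i, b in enumerate(ref):
            assert counts["ACGT".index(b), i] == 1
            assert counts[:, i].sum() == 1

    def test_disagreeing_reads_give_two_nonzero_counts(self):
        ref = "AAAAAAAA"
        alt = "AAAAGAAA"
        alns = [aligned("c", 0, ref, "r1"), aligned("c", 1, alt[1:], "r2")]
        counts = build_pileup(alns, "c", ref)
        col = counts[:, 4]
        assert col["ACGT".index("A")] == 1 and col["ACGT".index("G")] == 1

    def test_deletion_contributes_nothing_insertion_skipped(self):
        ref = "ACGTACGT"
        a = ReadAlignment(
            read_id="r", ref_id="c", ref_start=0, strand="+",
            operations=[("M", 2), ("D", 2), ("M", 2), ("I", 1), ("M", 2)],
            identity=1.0, aligned_fraction=1.0, score=6, query_start=0,
            query_end=7, oriented_sequence="ACACGGT",
        )
        counts = build_pileup([a], "c", ref)
        assert counts[:, 2].sum() == 0 and counts[:, 3].sum() == 0  # deleted
        assert counts[:, 0].sum() == 1 and counts[:, 7].sum() == 1


class TestCallSnps:
    @staticmethod
    def column(ref_count: int, alt_count: int, ref="A", alt="G"):
        depth = ref_count + alt_count
        seq = ref
        counts = np.zeros((4, 1), dtype=np.int32)
        counts["ACGT".index(ref), 0] = ref_count
        counts["ACGT".index(alt), 0] = alt_count
        return counts, seq

    @pytest.mark.parametrize(
        "ref_n,alt_n,called",
        [
            (4, 5, False),  # depth 9: below 10x
            (6, 4, True),  # depth 10, alt 0.40
            (14, 6, False),  # depth 20, alt 0.30
            (13, 7, True),  # depth 20, alt 0.35 inclusive
        ],
    )
    def test_depth_and_fraction_boundaries(self, ref_n, alt_n, called):
        counts, seq = self.column(ref_n, alt_n)
        calls = call_snps(counts, seq, "c")
        assert (len(calls) == 1) is called
        if called:
            assert calls[0].alt_allele == "G"
            assert calls[0].depth == ref_n + alt_n

    def test_brute_force_oracle_small_depths(self):
        """Exhaustive agreement with the stated rule for all depth <= 15
        pileup columns over a fixed reference base."""
        from itertools import product

        for c_a, c_c, c_g, c_t in product(range(16), repeat=4):
            depth = c_a + c_c + c_g + c_t
            if depth == 0 or depth > 15:
                continue
            counts = np.array([[c_a], [c_c], [c_g], [c_t]], dtype=np.int32)
            calls = call_snps(counts, "A", "c")
            top_alt = max(c_c, c_g, c_t)
            expected = depth >= 10 and top_alt / depth >= 0.35
            assert (len(calls) == 1) is expected, (c_a, c_c, c_g, c_t)

    def test_context_from_segments(self):
        counts, seq = self.column(6, 6)
        segs = [("exon", 0, 1)]
        assert call_snps(counts, seq, "c", segments=segs)[0].context == "exon"


class TestTsTv:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "G", "transition"), ("G", "A", "transition"),
         ("C", "T", "transition"), ("A", "C", "transversion"),
         ("T", "G", "transversion")],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_ts_tv(ref, alt) == expected

    def test_same_allele_rejected(self):
        with pytest.raises(ValueError):
            classify_ts_tv("A", "A")

    def test_partition_property(self, rng):
        """Transitions + transversions always equals the number of calls."""
        calls = []
        for _ in range(50):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            calls.append(snp("c", 0, str(ref), str(alt)))
        n_ts = sum(1 for c in calls if c.snp_class == "transition")
        n_tv = sum(1 for c in calls if c.snp_class == "transversion")
        assert n_ts + n_tv == len(calls)


class TestSnpFrequency:
    def test_ten_snps_per_kb_is_one_percent(self):
        snps = [snp("c", i, "A", "G") for i in range(10)]
        overall, per_contig, _ = snp_frequency(snps, {"c": 1000})
        assert overall == pytest.approx(1.0)
        assert per_contig["c"] == pytest.approx(1.0)

    def test_zero_snps(self):
        overall, per_contig, _ = snp_frequency([], {"c": 1000})
        assert overall == 0.0 and per_contig == {}

    def test_all_in_mask(self):
        snps = [snp("c", i, "A", "G") for i in (5, 15)]
        _, _, frac = snp_frequency(snps, {"c": 100}, {"c": [(0, 50)]})
        assert frac == 1.0


class TestIntersection:
    def test_identical_call_is_common(self):
        rep = intersect_snp_sets([snp("c", 5, "A", "G")],
                                 [snp("c", 5, "A", "G", "transcriptomic")])
        assert rep.n_common == 1
        assert rep.common[0].source == "common"
        assert rep.n_transitions == 1 and rep.n_transversions == 0

    def test_different_alt_not_common(self):
        rep = intersect_snp_sets([snp("c", 5, "A", "G")],
                                 [snp("c", 5, "A", "T", "transcriptomic")])
        assert rep.n_common == 0

    def test_liftover_through_hsp(self):
        # contig [100,300) aligns to transcript [0,200), forward
        hsp = HSP("t", 100, 300, 0, 200, 200, 1.0, "+", [("M", 200)])
        assert liftover_position([hsp], "t", 50) == ("+", 150)
        assert liftover_position([hsp], "t", 250) is None  # outside HSP

    def test_liftover_intersection_counts_unmappable(self):
        hsp = HSP("t", 100, 300, 0, 200, 200, 1.0, "+", [("M", 200)])
        genomic = [snp("c", 150, "A", "G")]
        transcript_calls = [snp("t", 50, "A", "G", "transcriptomic"),
                            snp("t", 500, "A", "G", "transcriptomic")]
        rep = intersect_snp_sets(genomic, transcript_calls, {"c": [hsp]})
        assert rep.n_common == 1
        assert rep.n_unmappable == 1
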