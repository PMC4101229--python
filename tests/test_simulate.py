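"""Synthetic-data generator: truth consistency under recount, determinism."""

import numpy as np
import pytest
from scipy import stats

from captureseq.mapping import ReferenceIndex, map_reads
from captureseq.simulate import (
    GeneModel,
    exon_capture_intervals,
    generate_genome,
    measured_duplicate_fraction,
    plant_variants,
    simulate_capture_reads,
    simulate_rnaseq_reads,
)
from captureseq.variants import build_pileup


class TestGeneModel:
    def test_exon_only_gene_transcript_equals_span(self):
        m = GeneModel("g", "c", [("exon", 100, 400)])
        assert m.span == 300 == m.transcript_length()

    def test_two_exons_one_intron_arithmetic(self):
        m = GeneModel(
            "g", "c",
            [("exon", 0, 200), ("intron", 200, 600), ("exon", 600, 900)],
        )
        assert m.span == 900
        assert m.transcript_length() == 500

    def test_invalid_structures_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", [("intron", 0, 100)])
        with pytest.raises(ValueError):
            GeneModel("g", "c", [("exon", 0, 100), ("exon", 100, 200)])
        with pytest.raises(ValueError):
            GeneModel("g", "c", [("exon", 0, 100), ("intron", 150, 200), ("exon", 200, 300)])


class TestGenerateGenome:
    def test_transcripts_are_exact_exon_concatenations(self):
        g = generate_genome(n_genes=5, seed=11)
        for m in g.gene_models:
            expected = "".join(g.contigs[m.contig_id][s:e] for s, e in m.exons())
            assert g.transcripts[m.gene_id] == expected

    def test_determinism(self):
        g1 = generate_genome(n_genes=4, n_microsat=3, seed=42)
        g2 = generate_genome(n_genes=4, n_microsat=3, seed=42)
        assert g1.contigs == g2.contigs
        assert g1.transcripts == g2.transcripts
        assert g1.microsats == g2.microsats

    def test_microsats_are_tandem_repeats_present_in_genome(self):
        g = generate_genome(n_genes=3, n_microsat=4, seed=5)
        joined = "".join(g.contigs.values())
        for tract in g.microsats.values():
            assert tract in joined
            # tandem structure: some motif of 2-6 bp whose repetition covers it
            assert any(
                tract == (tract[:k] * (len(tract) // k + 1))[: len(tract)]
                for k in range(2, 7)
            )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(0, seed=1)
        with pytest.raises(ValueError):
            generate_genome(1, exon_len_dist=(400, 100), seed=1)


class TestPlantVariants:
    def test_zero_rate_identical_haplotypes(self):
        g = generate_genome(n_genes=2, seed=3)
        h1, h2, truth = plant_variants(g, snp_rate=0.0, seed=4)
        assert h1 == g.contigs == h2
        assert truth == []

    def test_count_within_binomial_interval_and_recount(self):
        g = generate_genome(n_genes=40, seed=8)
        n = g.total_length()
        h1, h2, truth = plant_variants(g, snp_rate=0.01, seed=9)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= len(truth) <= hi
        # recount: every truth record is heterozygous with the stated alleles
        for rec in truth:
            ref = g.contigs[rec.contig_id][rec.position]
            b1 = h1[rec.contig_id][rec.position]
            b2 = h2[rec.contig_id][rec.position]
            assert rec.ref_allele == ref != rec.alt_allele
            assert {b1, b2} == {rec.ref_allele, rec.alt_allele}

    def test_rate_out_of_bounds(self):
        g = generate_genome(n_genes=1, seed=1)
        with pytest.raises(ValueError):
            plant_variants(g, snp_rate=0.2)


class TestCaptureReads:
    def test_duplicate_fraction_recount(self):
        g = generate_genome(n_genes=30, seed=21)
        h1, h2, _ = plant_variants(g, 0.005, seed=22)
        iv = exon_capture_intervals(g.gene_models)
        reads, _ = simulate_capture_reads(
            (h1, h2), iv, on_target_depth=120, off_target_depth=0.2,
            dup_rate=0.36, seed=23,
        )
        assert len(reads) >= 10000
        assert measured_duplicate_fraction(reads) == pytest.approx(0.36, abs=0.02)

    def test_off_target_zero_means_every_read_overlaps_capture(self):
        g = generate_genome(n_genes=4, seed=31)
        h1, h2, _ = plant_variants(g, 0.0, seed=32)
        iv = exon_capture_intervals(g.gene_models)
        reads, _ = simulate_capture_reads(
            (h1, h2), iv, on_target_depth=10, off_target_depth=0.0,
            dup_rate=0.0, error_rate=0.0, adapter="", seed=33,
        )
        # error-free, no duplicates: each read must be a substring of a
        # haplotype restricted to a window overlapping an exon
        from captureseq.align import revcomp

        for r in reads[:200]:
            seq = r.sequence
            found = False
            for cid, ivs in iv.items():
                hay = h1[cid]
                for probe_seq in (seq, revcomp(seq)):
                    pos = hay.find(probe_seq)
                    if pos < 0:
                        continue
                    for s, e in ivs:
                        if pos < e and pos + len(seq) > s:
                            found = True
            assert found

    def test_het_snp_alt_fraction_near_half(self):
        """At an error-free heterozygous site, the pileup alternate fraction
        stays inside the Binomial(depth, 0.5) 99% envelope."""
        g = generate_genome(n_genes=6, seed=41)
        h1, h2, truth = plant_variants(g, 0.004, seed=42)
        iv = exon_capture_intervals(g.gene_models)
        reads, _ = simulate_capture_reads(
            (h1, h2), iv, on_target_depth=40, off_target_depth=1.0,
            dup_rate=0.0, error_rate=0.0, adapter="", seed=43,
        )
        index = ReferenceIndex(g.contigs)
        alns = map_reads(reads, index)
        exonic = [t for t in truth if t.context == "exon"]
        assert exonic
        checked = 0
        for rec in exonic:
            counts = build_pileup(
                [a for a in alns if a.ref_id == rec.contig_id],
                rec.contig_id,
                g.contigs[rec.contig_id],
            )
            depth = int(counts[:, rec.position].sum())
            if depth < 20:
                continue
            alt = int(counts["ACGT".index(rec.alt_allele), rec.position])
            lo, hi = stats.binom.ppf([0.005, 0.995], depth, 0.5)
            assert lo <= alt <= hi, (rec, depth, alt)
            checked += 1
        assert checked >= 3

    def test_empty_probe_set_rejected(self):
        g = generate_genome(n_genes=1, seed=51)
        h1, h2, _ = plant_variants(g, 0.0, seed=52)
        with pytest.raises(ValueError, match="probe set"):
            simulate_capture_reads((h1, h2), {}, on_target_depth=5)


class TestRnaseqReads:
    def test_read_count_matches_depth(self):
        transcripts = {"t": "ACGT" * 125}  # 500 bp
        reads = simulate_rnaseq_reads(transcripts, depth=20, read_len=50, seed=6)
        assert len(reads) == pytest.approx(200, rel=0.1)

    def test_error_free_reads_are_exact_transcript_substrings(self):
        g = generate_genome(n_genes=3, seed=61)
        reads = simulate_rnaseq_reads(g.transcripts, depth=5, read_len=60,
                                      error_rate=0.0, seed=62)
        from captureseq.align import revcomp

        joined = list(g.transcripts.values())
        for r in reads:
            assert any(
                r.sequence in t or revcomp(r.sequence) in t for t in joined
            )

    def test_reads_never_span_intron_sequence(self):
        g = generate_genome(n_genes=3, exons_per_gene=(2, 3), seed=63)
        reads = simulate_rnaseq_reads(g.transcripts, depth=5, read_len=60,
                                      error_rate=0.0, seed=64)
        introns = [
            g.contigs[m.contig_id][s:e] for m in g.gene_models for s, e in m.introns()
        ]
        assert introns
        for r in reads[:300]:
            for intron in introns:
                assert r.sequence not in intron

    def test_read_len_too_long_rejected(self):
        with pytest.raises(ValueError, match="read_len"):
            simulate_rnaseq_reads({"t": "ACGT" * 10}, depth=1, read_len=100)
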