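"""File formats: FASTA/FASTQ via Biopython, plus thin SAM/VCF/GFF3/BED text writers.

Everything downstream works on in-memory objects; these helpers are the only
place the package touches files.  All coordinates written to BED are 0-based
half-open; GFF3 is 1-based inclusive; SAM POS is 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class SequenceRead:
    """A sequencing read with per-base Phred qualities and a run label."""

    read_id: str
    sequence: str
    qualities: list[int]
    run_label: str = "RUN_1"

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, run_label: str = "RUN_1") -> list[SequenceRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SequenceRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                run_label=run_label,
            )
        )
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ------------------------------------------------------------------------ SAM


def write_sam(alignments, references: Mapping[str, str], path: str | Path) -> None:
    """Write mapped-read placements as plain SAM text (no BAM plumbing)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:captureseq\tPN:captureseq\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            cigar = "".join(f"{l}{_SAM_OP[op]}" for op, l in aln.operations)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.ref_start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t*\t*\tNM:i:{aln.n_mismatches}\n"
            )


_SAM_OP = {"M": "=", "X": "X", "I": "I", "D": "D"}


# ------------------------------------------------------------------------ VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##INFO=<ID=CLASS,Number=1,Type=String,Description="transition or transversion">
##INFO=<ID=CTX,Number=1,Type=String,Description="exon, intron or unknown context">
##INFO=<ID=SRC,Number=1,Type=String,Description="genomic, transcriptomic or common">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(snps, path: str | Path, contigs: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, seq in contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(VCF_HEADER.split("\n", 1)[1])
        for s in snps:
            info = (
                f"DP={s.depth};AF={s.alt_fraction:.4f};CLASS={s.snp_class};"
                f"CTX={s.context};SRC={s.source}"
            )
            fh.write(
                f"{s.contig_id}\t{s.position + 1}\t.\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t{info}\n"
            )


# ------------------------------------------------------------------- GFF/BED


def write_gff3(features, path: str | Path) -> None:
    """features: iterable of (contig_id, source, ftype, start0, end0, attrs dict)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, source, ftype, start, end, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{contig_id}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t+\t.\t{attr_str}\n"
            )


def write_bed(intervals, path: str | Path) -> None:
    """intervals: iterable of (contig_id, start0, end0, name)."""
    with open(path, "w") as fh:
        for contig_id, start, end, name in intervals:
            fh.write(f"{contig_id}\t{start}\t{end}\t{name}\n")


def write_bedgraph(depth_by_contig: Mapping[str, "list[int]"], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig_id, depth in depth_by_contig.items():
            run_start = 0
            for pos in range(1, len(depth) + 1):
                if pos == len(depth) or depth[pos] != depth[run_start]:
                    fh.write(f"{contig_id}\t{run_start}\t{pos}\t{depth[run_start]}\n")
                    run_start = pos


# ----------------------------------------------------------------------- misc


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
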