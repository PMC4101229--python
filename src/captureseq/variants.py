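"""Threshold-based SNP calling from read pileups, and call-set intersection.

A variant is reported when the pileup depth is at least 10 and the most
frequent non-reference base accounts for at least 35% of the locally aligned
reads (both boundaries inclusive).  Reads with identical mapping location
(reference, start, strand, aligned read length) are collapsed to one before
counting, to damp PCR-amplification artefacts.  Calls are classified as
transitions (A<->G, C<->T) or transversions and localised to exon/intron
context when gene segments are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genestruct import HSP
from .mapping import ReadAlignment

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def build_pileup(
    alignments: Sequence[ReadAlignment], contig_id: str, contig_seq: str
) -> np.ndarray:
    """Per-position base counts (4 x L) from accepted alignments.

    Alignments sharing (ref_start, strand, aligned read length) are counted
    once; deletions contribute nothing and inserted read bases are skipped.
    """
    counts = np.zeros((4, len(contig_seq)), dtype=np.int32)
    seen: set[tuple[int, str, int]] = set()
    for aln in alignments:
        if aln.ref_id != contig_id:
            continue
        key = (aln.ref_start, aln.strand, len(aln.oriented_sequence))
        if key in seen:
            continue
        seen.add(key)
        qpos = aln.query_start
        rpos = aln.ref_start
        seq = aln.oriented_sequence
        for op, length in aln.operations:
            if op in "MX":
                for i in range(length):
                    b = _BASE_IDX.get(seq[qpos + i])
                    if b is not None:
                        counts[b, rpos + i] += 1
                qpos += length
                rpos += length
            elif op == "I":
                qpos += length
            elif op == "D":
                rpos += length
    return counts


def classify_ts_tv(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) or transversion."""
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


@dataclass
class SNPCall:
    contig_id: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float
    snp_class: str  # transition | transversion
    context: str = "unknown"  # exon | intron | unknown
    source: str = "genomic"  # genomic | transcriptomic | common
    multiallelic: bool = False


def call_snps(
    counts: np.ndarray,
    contig_seq: str,
    contig_id: str,
    min_depth: int = 10,
    min_alt_fraction: float = 0.35,
    segments: Sequence[tuple[str, int, int]] | None = None,
    source: str = "genomic",
) -> list[SNPCall]:
    """Emit one biallelic call per position passing depth and fraction rules.

    A call requires depth >= ``min_depth`` and top non-reference base
    fraction >= ``min_alt_fraction`` (inclusive).  Columns where a second
    non-reference base also clears the fraction are flagged multiallelic but
    still report only the top alternate.
    """
    calls: list[SNPCall] = []
    depth_vec = counts.sum(axis=0)
    candidate_positions = np.nonzero(depth_vec >= min_depth)[0]
    for pos in candidate_positions:
        ref = contig_seq[pos]
        ref_idx = _BASE_IDX.get(ref)
        if ref_idx is None:
            continue
        depth = int(depth_vec[pos])
        col = counts[:, pos].copy()
        col[ref_idx] = -1  # exclude reference from the alt argmax
        alt_idx = int(np.argmax(col))
        alt_count = int(counts[alt_idx, pos])
        if alt_count / depth < min_alt_fraction:
            continue
        second = sorted(
            (int(c) for i, c in enumerate(counts[:, pos]) if i not in (ref_idx, alt_idx)),
            reverse=True,
        )
        multi = bool(second and second[0] / depth >= min_alt_fraction)
        alt = _IDX_BASE[alt_idx]
        context = "unknown"
        if segments is not None:
            for kind, s, e in segments:
                if s <= pos < e:
                    context = kind if kind in ("exon", "intron") else "unknown"
                    break
        calls.append(
            SNPCall(
                contig_id=contig_id,
                position=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                depth=depth,
                alt_fraction=alt_count / depth,
                snp_class=classify_ts_tv(ref, alt),
                context=context,
                source=source,
                multiallelic=multi,
            )
        )
    return calls


def snp_frequency(
    snps: Sequence[SNPCall],
    contig_lengths: Mapping[str, int],
    region_mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[float, dict[str, float], float]:
    """Overall and per-contig SNP frequency (%), and the fraction in exons.

    Overall frequency is 100 * n_snps / total contig length; the denominator
    (total assembled bases) is printed by callers alongside the figure.
    """
    total_bp = sum(contig_lengths.values())
    if total_bp <= 0:
        raise ValueError("contig lengths must be positive")
    per_contig_counts: dict[str, int] = {}
    for s in snps:
        if s.contig_id not in contig_lengths:
            raise ValueError(f"SNP on unknown contig {s.contig_id!r}")
        per_contig_counts[s.contig_id] = per_contig_counts.get(s.contig_id, 0) + 1
    overall = 100.0 * len(snps) / total_bp
    per_contig = {
        cid: 100.0 * n / contig_lengths[cid] for cid, n in per_contig_counts.items()
    }
    in_mask = 0
    if region_mask is not None and snps:
        for s in snps:
            for a, b in region_mask.get(s.contig_id, ()):
                if a <= s.position < b:
                    in_mask += 1
                    break
        exon_fraction = in_mask / len(snps)
    else:
        exon_fraction = float("nan")
    return overall, per_contig, exon_fraction


# ------------------------------------------------------------------ liftover


def liftover_position(hsps: Sequence[HSP], target_id: str, subject_pos: int) -> tuple[str, int] | None:
    """Map a transcript position to contig coordinates through HSP columns.

    Returns (strand, contig_position) or None when no HSP covers the
    position or it falls in a transcript-only (deleted) stretch.
    """
    for h in hsps:
        if h.target_id != target_id:
            continue
        if not h.subject_start <= subject_pos < h.subject_end:
            continue
        qpos, spos = h.query_start, h.subject_start
        if h.strand == "-":
            qpos = h.query_end  # walk leftwards on the contig
        for op, length in h.operations:
            if op in "MX":
                if spos <= subject_pos < spos + length:
                    off = subject_pos - spos
                    if h.strand == "+":
                        return "+", qpos + off
                    return "-", qpos - off - 1
                spos += length
                qpos = qpos + length if h.strand == "+" else qpos - length
            elif op == "I":
                qpos = qpos + length if h.strand == "+" else qpos - length
            elif op == "D":
                if spos <= subject_pos < spos + length:
                    return None  # transcript-only stretch, no contig base
                spos += length
    return None


@dataclass
class IntersectionReport:
    common: list = field(default_factory=list)
    n_genomic: int = 0
    n_transcriptomic: int = 0
    n_common: int = 0
    n_contigs_with_common: int = 0
    n_transitions: int = 0
    n_transversions: int = 0
    n_unmappable: int = 0


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def intersect_snp_sets(
    genomic_snps: Sequence[SNPCall],
    transcriptomic_snps: Sequence[SNPCall],
    coordinate_map: Mapping[str, Sequence[HSP]] | None = None,
) -> IntersectionReport:
    """Calls present in both sets at equivalent coordinates with the same alt.

    When both sets are already in contig coordinates, equivalence is exact
    (contig, position, alt).  When the transcriptomic calls are in transcript
    coordinates, ``coordinate_map`` (contig id -> HSPs against transcripts)
    lifts them onto contigs first; unmappable calls are counted separately.
    """
    report = IntersectionReport(
        n_genomic=len(genomic_snps), n_transcriptomic=len(transcriptomic_snps)
    )
    lifted: list[tuple[str, int, str]] = []
    if coordinate_map is None:
        lifted = [
            (s.contig_id, s.position, s.alt_allele) for s in transcriptomic_snps
        ]
    else:
        for s in transcriptomic_snps:
            hit = None
            for contig_id, hsps in coordinate_map.items():
                res = liftover_position(hsps, s.contig_id, s.position)
                if res is not None:
                    strand, cpos = res
                    alt = s.alt_allele if strand == "+" else _COMPLEMENT[s.alt_allele]
                    hit = (contig_id, cpos, alt)
                    break
            if hit is None:
                report.n_unmappable += 1
            else:
                lifted.append(hit)
    trans_keys = set(lifted)
    for s in genomic_snps:
        if (s.contig_id, s.position, s.alt_allele) in trans_keys:
            common = SNPCall(
                contig_id=s.contig_id,
                position=s.position,
                ref_allele=s.ref_allele,
                alt_allele=s.alt_allele,
                depth=s.depth,
                alt_fraction=s.alt_fraction,
                snp_class=s.snp_class,
                context=s.context,
                source="common",
                multiallelic=s.multiallelic,
            )
            report.common.append(common)
    report.n_common = len(report.common)
    report.n_contigs_with_common = len({s.contig_id for s in report.common})
    report.n_transitions = sum(
        1 for s in report.common if s.snp_class == "transition"
    )
    report.n_transversions = report.n_common - report.n_transitions
    return report
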