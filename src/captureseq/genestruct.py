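"""RNA-seq-guided gene structure: coverage segmentation and intron discovery.

Genomic contigs are segmented from RNA-seq back-mapping coverage: internal
zero-coverage runs of at least ``min_gap`` bp are intron segments (RNA-seq
reads come from spliced transcripts, so introns receive no coverage), while
zero-coverage runs touching a contig end are unresolved flanks.  Contigs
whose uncovered span is at least 250 bp are intron candidates; aligning a
candidate against the transcript targets yields high-scoring segment pairs
(HSPs), and a pair of query-adjacent, subject-adjacent HSPs to the same
transcript brackets a fully sequenced intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import revcomp, smith_waterman
from .mapping import ReadAlignment


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])

    @property
    def covered_length(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def covered_fraction(self) -> float:
        return self.covered_length / self.length if self.length else 0.0


def coverage_profile(
    alignments: Sequence[ReadAlignment], contig_id: str, contig_length: int
) -> CoverageProfile:
    """Per-base RNA-seq depth on one genomic contig from accepted alignments."""
    depth = np.zeros(contig_length, dtype=np.int32)
    for aln in alignments:
        if aln.ref_id != contig_id:
            continue
        rpos = aln.ref_start
        for op, length in aln.operations:
            if op in "MX":
                depth[rpos : rpos + length] += 1
                rpos += length
            elif op == "D":
                rpos += length
    return CoverageProfile(contig_id, depth)


def call_segments(
    profile: CoverageProfile, min_gap: int = 100, min_exon: int = 20
) -> list[tuple[str, int, int]]:
    """Partition a contig into exon / intron / unresolved_flank segments.

    Internal zero-depth runs >= ``min_gap`` become introns; zero-depth runs
    touching an end (>= ``min_exon`` long) become unresolved flanks; shorter
    zero runs are absorbed into exon segments.  Exon slivers shorter than
    ``min_exon`` caught between non-exon segments are merged into them.
    The returned segments always tile [0, length).
    """
    n = profile.length
    if n == 0:
        return []
    zero = profile.depth == 0
    # maximal zero runs
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # classify runs
    keep: list[tuple[str, int, int]] = []
    for s, e in runs:
        touches_end = s == 0 or e == n
        if touches_end and e - s >= min_exon:
            keep.append(("unresolved_flank", s, e))
        elif not touches_end and e - s >= min_gap:
            keep.append(("intron", s, e))
    # fill exons between kept runs
    segments: list[tuple[str, int, int]] = []
    pos = 0
    for kind, s, e in keep:
        if s > pos:
            segments.append(("exon", pos, s))
        segments.append((kind, s, e))
        pos = e
    if pos < n:
        segments.append(("exon", pos, n))
    # merge exon slivers between non-exon neighbours
    merged: list[tuple[str, int, int]] = []
    for seg in segments:
        if (
            seg[0] == "exon"
            and seg[2] - seg[1] < min_exon
            and merged
            and merged[-1][0] != "exon"
        ):
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], seg[2])
        elif (
            seg[0] != "exon"
            and merged
            and merged[-1][0] == seg[0]
        ):
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], seg[2])
        else:
            merged.append(seg)
    return merged


def candidate_intron_contigs(
    profiles: Mapping[str, CoverageProfile], min_divergence: int = 250
) -> list[str]:
    """Contig ids whose uncovered span (length - covered) is >= min_divergence."""
    return [
        cid
        for cid, p in profiles.items()
        if p.length - p.covered_length >= min_divergence
    ]


@dataclass
class HSP:
    """A high-scoring segment pair between a genomic contig and a transcript."""

    target_id: str
    query_start: int  # on the genomic contig, 0-based half-open
    query_end: int
    subject_start: int  # on the transcript
    subject_end: int
    score: int
    identity: float
    strand: str  # contig strand relative to the transcript
    operations: list = field(default_factory=list)


def _iterative_hsps(
    query: str,
    target_id: str,
    target_seq: str,
    min_score: int,
    min_identity: float,
    max_hsps: int,
) -> list[HSP]:
    hsps: list[HSP] = []
    masked = query
    for _ in range(max_hsps):
        aln = smith_waterman(masked, target_seq)
        if aln is None or aln.score < min_score:
            break
        identity = aln.identity_over_query()
        if identity >= min_identity:
            hsps.append(
                HSP(
                    target_id=target_id,
                    query_start=aln.query_start,
                    query_end=aln.query_end,
                    subject_start=aln.ref_start,
                    subject_end=aln.ref_end,
                    score=aln.score,
                    identity=identity,
                    strand="+",
                    operations=list(aln.operations),
                )
            )
        # mask the query span so the next round finds a disjoint HSP
        masked = (
            masked[: aln.query_start]
            + "N" * aln.query_span
            + masked[aln.query_end :]
        )
    return hsps


def align_contig_to_targets(
    contig_seq: str,
    targets: Mapping[str, str],
    min_hsp_score: int = 30,
    min_hsp_identity: float = 0.8,
    one_hsp_per_locus: bool = True,
    max_hsps: int = 20,
) -> list[HSP]:
    """All non-overlapping HSPs between a contig and each transcript target.

    Per target the contig is aligned iteratively, masking each HSP's query
    span, so each contig locus contributes one HSP (the best-scoring local
    alignment there); both contig orientations are tried and the better one
    kept.  HSPs are returned sorted by query coordinate.
    """
    del one_hsp_per_locus  # masking enforces it; kept for interface clarity
    out: list[HSP] = []
    L = len(contig_seq)
    rc = revcomp(contig_seq)
    for tid in sorted(targets):
        fwd = _iterative_hsps(
            contig_seq, tid, targets[tid], min_hsp_score, min_hsp_identity, max_hsps
        )
        rev = _iterative_hsps(
            rc, tid, targets[tid], min_hsp_score, min_hsp_identity, max_hsps
        )
        if sum(h.score for h in rev) > sum(h.score for h in fwd):
            for h in rev:
                qs, qe = h.query_start, h.query_end
                h.query_start, h.query_end = L - qe, L - qs
                h.strand = "-"
            out.extend(rev)
        else:
            out.extend(fwd)
    out.sort(key=lambda h: (h.query_start, h.query_end, h.target_id))
    return out


@dataclass
class IntronCall:
    contig_id: str
    start: int  # 0-based half-open on the contig
    end: int
    complete: bool
    target_id: str
    flanking_hsps: tuple | None = None
    splice_motif: str = ""  # first two + last two intron bases, annotation only

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_complete_introns(
    contig_id: str,
    contig_seq: str,
    hsps: Sequence[HSP],
    segments: Sequence[tuple[str, int, int]] | None = None,
    subject_gap_tolerance: int = 10,
) -> list[IntronCall]:
    """Introns bracketed by subject-adjacent HSP pairs to the same transcript.

    For each pair of query-adjacent HSPs matching the same target on the same
    strand whose transcript intervals are adjacent (gap or overlap at most
    ``subject_gap_tolerance`` bp), the contig interval between them is a
    fully sequenced intron, marked complete when it lies strictly inside the
    contig.  Splice motifs (e.g. GT..AG) are annotated, never filtered on.
    """
    del segments  # coverage agreement is asserted by callers, not filtered here
    calls: list[IntronCall] = []
    L = len(contig_seq)
    by_target: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_target.setdefault((h.target_id, h.strand), []).append(h)
    for (tid, strand), group in sorted(by_target.items()):
        group = sorted(group, key=lambda h: h.query_start)
        for h1, h2 in zip(group, group[1:]):
            if h2.query_start <= h1.query_end:
                continue  # overlapping query intervals: no clean intron between
            if strand == "+":
                gap = h2.subject_start - h1.subject_end
            else:
                gap = h1.subject_start - h2.subject_end
            if abs(gap) > subject_gap_tolerance:
                continue
            start, end = h1.query_end, h2.query_start
            motif = ""
            if end - start >= 4:
                intron_seq = contig_seq[start:end]
                if strand == "-":
                    intron_seq = revcomp(intron_seq)
                motif = intron_seq[:2] + ".." + intron_seq[-2:]
            calls.append(
                IntronCall(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    complete=start > 0 and end < L,
                    target_id=tid,
                    flanking_hsps=(h1, h2),
                    splice_motif=motif,
                )
            )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


@dataclass
class IntronStats:
    n_contigs_with_introns: int
    n_introns: int
    total_length: int
    mean_length: float
    max_length: int
    min_length: int


def intron_stats(calls: Sequence[IntronCall], complete_only: bool = True) -> IntronStats:
    """Summary over intron calls (complete ones by default)."""
    kept = [c for c in calls if c.complete] if complete_only else list(calls)
    if not kept:
        return IntronStats(0, 0, 0, 0.0, 0, 0)
    lengths = [c.length for c in kept]
    return IntronStats(
        n_contigs_with_introns=len({c.contig_id for c in kept}),
        n_introns=len(kept),
        total_length=sum(lengths),
        mean_length=sum(lengths) / len(lengths),
        max_length=max(lengths),
        min_length=min(lengths),
    )
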