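"""Read mapping with explicit acceptance thresholds, and enrichment reports.

The mapper is seed-and-extend: shared k-mers (both strands) nominate
reference windows, the best window is aligned by Smith-Waterman with
mismatch cost 2 and gap cost 3, and the alignment is accepted iff at least
half of the read aligns (length fraction >= 0.5) and at least 80% of the
aligned read bases match the reference (similarity >= 0.8).  Those two
thresholds, not the engine, define on-target status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import LocalAlignment, encode, revcomp, smith_waterman
from .io import SequenceRead


@dataclass
class ReadAlignment:
    """Accepted placement of a read on a reference sequence."""

    read_id: str
    ref_id: str
    ref_start: int  # 0-based
    strand: str  # '+' or '-'
    operations: list  # [(op, length)]; op in M X I D, along the reference
    identity: float  # matching columns / aligned read bases
    aligned_fraction: float  # aligned read bases / read length
    score: int
    query_start: int  # on the oriented read
    query_end: int
    oriented_sequence: str  # read sequence in reference orientation
    ambiguous: bool = False

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(l for op, l in self.operations if op in "MXD")

    @property
    def n_mismatches(self) -> int:
        return sum(l for op, l in self.operations if op in "XID")

    @property
    def aligned_read_bases(self) -> int:
        return self.query_end - self.query_start


class ReferenceIndex:
    """k-mer index over a reference set, shared by mapping and repeat filtering."""

    def __init__(self, references: Mapping[str, str], k: int = 13):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.references = {rid: seq.upper() for rid, seq in references.items()}
        self.encoded = {rid: encode(seq) for rid, seq in self.references.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.references.items():
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((rid, pos))


def _candidate_windows(
    index: ReferenceIndex, query: str, max_candidates: int = 8
) -> list[tuple[str, int, int]]:
    """Nominate (ref_id, window_start, window_end) from seed diagonals."""
    k = index.k
    qlen = len(query)
    diags_by_ref: dict[str, list[int]] = {}
    for qpos in range(0, qlen - k + 1):
        for rid, rpos in index.kmers.get(query[qpos : qpos + k], ()):
            diags_by_ref.setdefault(rid, []).append(rpos - qpos)
    if not diags_by_ref:
        return []
    # cluster seed diagonals; each cluster nominates one alignment window
    clusters: list[tuple[int, str, int, int]] = []  # (-n_seeds, rid, lo, hi)
    for rid, diags in diags_by_ref.items():
        diags.sort()
        start = 0
        for i in range(1, len(diags) + 1):
            if i == len(diags) or diags[i] - diags[i - 1] > 32:
                clusters.append((-(i - start), rid, diags[start], diags[i - 1]))
                start = i
    clusters.sort()
    pad = qlen // 2 + 20
    windows: list[tuple[str, int, int]] = []
    seen: set[tuple[str, int, int]] = set()
    for _neg, rid, dmin, dmax in clusters[:max_candidates]:
        rlen = len(index.references[rid])
        win = (rid, max(0, dmin - pad), min(rlen, dmax + qlen + pad))
        if win not in seen:
            seen.add(win)
            windows.append(win)
    return windows


def map_read(
    read: SequenceRead | str,
    index: ReferenceIndex,
    mismatch_cost: int = 2,
    gap_cost: int = 3,
    min_length_fraction: float = 0.5,
    min_similarity: float = 0.8,
    exhaustive: bool = False,
) -> ReadAlignment | None:
    """Best accepted alignment of a read against the indexed references.

    Returns None when the read is shorter than the seed length, shares no
    seed with any reference, or no candidate passes the length-fraction and
    similarity thresholds.  Among accepted candidates the lowest-cost
    (highest-score) one wins; ties break by (ref_id, leftmost ref_start);
    reads with multiple distinct best placements are flagged ambiguous.

    ``exhaustive=True`` aligns against every reference in full instead of
    seed-nominated windows, making the accept/reject decision exact at the
    cost of speed; the seeded path falls back to a full scan for a strand
    only when that strand shares no seed with any reference.
    """
    if isinstance(read, SequenceRead):
        read_id, seq = read.read_id, read.sequence.upper()
    else:
        read_id, seq = "query", read.upper()
    if not exhaustive and len(seq) < index.k:
        return None
    full_scan = [
        (rid, 0, len(r)) for rid, r in index.references.items()
    ]

    candidates: list[ReadAlignment] = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        windows = full_scan if exhaustive else (
            _candidate_windows(index, oriented) or full_scan
        )
        for rid, lo, hi in windows:
            aln = smith_waterman(
                oriented,
                index.references[rid][lo:hi],
                mismatch_cost=mismatch_cost,
                gap_cost=gap_cost,
            )
            if aln is None or aln.query_span == 0:
                continue
            fraction = aln.query_span / len(seq)
            identity = aln.identity_over_query()
            if fraction < min_length_fraction or identity < min_similarity:
                continue
            candidates.append(
                ReadAlignment(
                    read_id=read_id,
                    ref_id=rid,
                    ref_start=lo + aln.ref_start,
                    strand=strand,
                    operations=list(aln.operations),
                    identity=identity,
                    aligned_fraction=fraction,
                    score=aln.score,
                    query_start=aln.query_start,
                    query_end=aln.query_end,
                    oriented_sequence=oriented,
                )
            )
    if not candidates:
        return None
    candidates.sort(key=lambda a: (-a.score, a.ref_id, a.ref_start))
    best = candidates[0]
    ties = [
        c
        for c in candidates
        if c.score == best.score
        and (c.ref_id, c.ref_start, c.strand) != (best.ref_id, best.ref_start, best.strand)
    ]
    if ties:
        best.ambiguous = True
    return best


def map_reads(
    reads: Iterable[SequenceRead],
    index: ReferenceIndex,
    drop_ambiguous: bool = False,
    **kwargs,
) -> list[ReadAlignment]:
    out = []
    for r in reads:
        aln = map_read(r, index, **kwargs)
        if aln is not None and not (drop_ambiguous and aln.ambiguous):
            out.append(aln)
    return out


# ------------------------------------------------------------------ coverage

DEFAULT_COVERAGE_BINS = (0.0, 1.0, 5.0, 10.0, 50.0)


@dataclass
class TargetCoverage:
    target_id: str
    length: int
    read_count: int
    aligned_bases: int

    @property
    def mean_depth(self) -> float:
        return self.aligned_bases / self.length if self.length else 0.0

    @property
    def covered(self) -> bool:
        return self.read_count >= 1


def target_coverage(
    alignments: Sequence[ReadAlignment],
    targets: Mapping[str, str],
    bins: Sequence[float] = DEFAULT_COVERAGE_BINS,
) -> tuple[dict[str, TargetCoverage], int, dict[str, int]]:
    """Per-target read counts and mean depth, plus a coverage-class histogram.

    Mean depth is aligned read bases on the target divided by target length;
    a target is covered when at least one accepted read aligns to it.
    Histogram classes are 0, (b0,b1], ..., > b_last over mean depth.
    """
    per_target = {
        tid: TargetCoverage(tid, len(seq), 0, 0) for tid, seq in targets.items()
    }
    for aln in alignments:
        if aln.ref_id not in per_target:
            raise ValueError(f"alignment references unknown target {aln.ref_id!r}")
        tc = per_target[aln.ref_id]
        tc.read_count += 1
        tc.aligned_bases += sum(l for op, l in aln.operations if op in "MX")
    labels = ["0"] + [
        f"({bins[i]:g},{bins[i + 1]:g}]" for i in range(len(bins) - 1)
    ] + [f">{bins[-1]:g}"]
    hist = {lab: 0 for lab in labels}
    for tc in per_target.values():
        d = tc.mean_depth
        if tc.read_count == 0:
            hist["0"] += 1
        else:
            placed = False
            for i in range(len(bins) - 1):
                if bins[i] < d <= bins[i + 1]:
                    hist[labels[i + 1]] += 1
                    placed = True
                    break
            if not placed:
                hist[labels[-1]] += 1
    n_covered = sum(1 for tc in per_target.values() if tc.covered)
    return per_target, n_covered, hist


def capture_efficiency(n_on_target: int, n_hq: int) -> float:
    """Percentage of high-quality reads whose accepted alignment is on-target."""
    if n_hq <= 0:
        raise ValueError("n_hq must be positive")
    if n_on_target > n_hq:
        raise ValueError("n_on_target cannot exceed n_hq")
    return 100.0 * n_on_target / n_hq


@dataclass
class EnrichmentReport:
    run_label: str
    n_total: int
    n_hq: int
    n_on_target: int
    n_targets: int
    n_covered_targets: int
    coverage_histogram: dict[str, int] = field(default_factory=dict)

    @property
    def capture_efficiency(self) -> float:
        return capture_efficiency(self.n_on_target, self.n_hq)

    @property
    def capture_efficiency_rounded(self) -> int:
        return int(round(self.capture_efficiency))

    def to_dict(self) -> dict:
        return {
            "run": self.run_label,
            "total_reads": self.n_total,
            "hq_reads": self.n_hq,
            "on_target_reads": self.n_on_target,
            "capture_efficiency_pct": self.capture_efficiency,
            "capture_efficiency_pct_rounded": self.capture_efficiency_rounded,
            "n_targets": self.n_targets,
            "n_covered_targets": self.n_covered_targets,
            "covered_targets_pct": 100.0 * self.n_covered_targets / self.n_targets
            if self.n_targets
            else 0.0,
            "coverage_histogram": self.coverage_histogram,
        }


def enrichment_report(
    run_label: str,
    n_total: int,
    hq_reads: Sequence[SequenceRead],
    alignments: Sequence[ReadAlignment],
    targets: Mapping[str, str],
    bins: Sequence[float] = DEFAULT_COVERAGE_BINS,
) -> EnrichmentReport:
    _per_target, n_covered, hist = target_coverage(alignments, targets, bins)
    return EnrichmentReport(
        run_label=run_label,
        n_total=n_total,
        n_hq=len(hq_reads),
        n_on_target=len(alignments),
        n_targets=len(targets),
        n_covered_targets=n_covered,
        coverage_histogram=hist,
    )


def plot_coverage_classes(histogram: Mapping[str, int], path: str) -> None:
    """Bar chart of the number of targets per coverage class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(histogram.keys()), list(histogram.values()), color="#4878d0")
    ax.set_xlabel("mean coverage class")
    ax.set_ylabel("number of targets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
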