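"""Capture-read quality control.

Filter chain (fixed order): adapter trimming -> mean-quality filter
(> Q20, strict) -> length filter (> 50 nt, strict) -> N filter (at most
one N) -> exact-duplicate removal -> microsatellite-repeat exclusion.
Clonality is the fraction of reads that are exact sequence copies of an
earlier read, an estimate of PCR amplification artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import SequenceRead
from .mapping import ReferenceIndex, map_read


def trim_adapters(
    read: SequenceRead,
    adapters: Sequence[str],
    min_overlap: int = 8,
    max_mismatch_frac: float = 0.1,
) -> SequenceRead:
    """Remove the longest 3' suffix matching any adapter prefix.

    A suffix of length ``o >= min_overlap`` is removed when it matches the
    first ``o`` bases of an adapter with at most ``max_mismatch_frac * o``
    mismatches; qualities are trimmed in lockstep.
    """
    seq = read.sequence
    best = 0
    for adapter in adapters:
        adapter = adapter.upper()
        max_o = min(len(seq), len(adapter))
        for o in range(max_o, min_overlap - 1, -1):
            if o <= best:
                break
            suffix = seq[-o:]
            mism = sum(1 for a, b in zip(suffix, adapter[:o]) if a != b)
            if mism <= max_mismatch_frac * o:
                best = o
                break
    if best == 0:
        return read
    return SequenceRead(
        read.read_id,
        seq[:-best],
        list(read.qualities[:-best]),
        run_label=read.run_label,
    )


def quality_filter(
    read: SequenceRead, min_mean_q: float = 20.0, mode: str = "mean"
) -> bool:
    """True iff read quality exceeds ``min_mean_q`` (strict).

    ``mode="mean"`` uses the arithmetic mean Phred score; ``mode="min"``
    requires every base to exceed the cutoff.  Empty reads fail.
    """
    if not read.qualities:
        return False
    if mode == "mean":
        return read.mean_quality() > min_mean_q
    if mode == "min":
        return min(read.qualities) > min_mean_q
    raise ValueError(f"unknown quality mode {mode!r}")


def length_and_n_filter(read: SequenceRead, min_len: int = 50, max_n: int = 1) -> bool:
    """True iff length > min_len (strict) and the read has at most max_n Ns."""
    return len(read) > min_len and read.sequence.count("N") <= max_n


def deduplicate(reads: Sequence[SequenceRead]) -> tuple[list[SequenceRead], float]:
    """Collapse exact-sequence duplicates to first occurrence; report clonality.

    clonality = (n_input - n_unique) / n_input.
    """
    seen: set[str] = set()
    unique: list[SequenceRead] = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            unique.append(r)
    clonality = (len(reads) - len(unique)) / len(reads) if reads else 0.0
    return unique, clonality


def repeat_filter(
    reads: Sequence[SequenceRead],
    repeat_index: ReferenceIndex | None,
    **mapper_kwargs,
) -> list[SequenceRead]:
    """Drop reads whose best alignment to the repeat library is accepted.

    Acceptance uses the same length-fraction/similarity thresholds as target
    mapping, so only reads that are mostly repeat sequence are excluded.
    """
    if repeat_index is None or not repeat_index.references:
        return list(reads)
    kept = []
    for r in reads:
        if map_read(r, repeat_index, **mapper_kwargs) is None:
            kept.append(r)
    return kept


@dataclass
class QCReport:
    n_input: int = 0
    n_pass_quality: int = 0
    n_pass_length: int = 0
    n_pass_n_filter: int = 0
    n_after_dedup: int = 0
    n_after_repeat_filter: int = 0
    clonality: float = 0.0
    per_run: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_quality": self.n_pass_quality,
            "n_pass_length": self.n_pass_length,
            "n_pass_n_filter": self.n_pass_n_filter,
            "n_after_dedup": self.n_after_dedup,
            "n_after_repeat_filter": self.n_after_repeat_filter,
            "clonality": self.clonality,
            "per_run": self.per_run,
        }


def run_qc(
    reads: Sequence[SequenceRead],
    adapters: Sequence[str] = (),
    repeat_index: ReferenceIndex | None = None,
    min_mean_q: float = 20.0,
    quality_mode: str = "mean",
    min_len: int = 50,
    max_n: int = 1,
    adapter_min_overlap: int = 8,
    adapter_max_mismatch_frac: float = 0.1,
) -> tuple[list[SequenceRead], QCReport]:
    """Apply the full filter chain and count survivors at each stage."""
    report = QCReport(n_input=len(reads))
    trimmed = [
        trim_adapters(r, adapters, adapter_min_overlap, adapter_max_mismatch_frac)
        if adapters
        else r
        for r in reads
    ]
    q_pass = [r for r in trimmed if quality_filter(r, min_mean_q, quality_mode)]
    report.n_pass_quality = len(q_pass)
    len_pass = [r for r in q_pass if len(r) > min_len]
    report.n_pass_length = len(len_pass)
    n_pass = [r for r in len_pass if r.sequence.count("N") <= max_n]
    report.n_pass_n_filter = len(n_pass)
    unique, clonality = deduplicate(n_pass)
    report.n_after_dedup = len(unique)
    report.clonality = clonality
    final = repeat_filter(unique, repeat_index)
    report.n_after_repeat_filter = len(final)
    runs = sorted({r.run_label for r in reads})
    for run in runs:
        report.per_run[run] = {
            "n_input": sum(1 for r in reads if r.run_label == run),
            "n_hq": sum(1 for r in final if r.run_label == run),
        }
    return final, report
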