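"""Greedy overlap-layout-consensus assembly of QC-passed reads.

The assembler repeatedly merges the pair of sequences (reads or growing
contigs) with the longest suffix-prefix overlap of at least ``min_overlap``
bases at ``min_overlap_identity`` or better, considering both strands; ties
break by higher identity, then lexicographic id.  Consensus is per-column
majority over base counts; contained sequences are absorbed.  Candidate
overlaps are nominated by shared k-mers and verified by direct comparison,
so the greedy choice is exact among nominated candidates.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .io import SequenceRead

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_DEC = np.array(list("ACGTN"))
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return "".join(_DEC[arr])


@dataclass
class AssembledContig:
    contig_id: str
    sequence: str
    n_reads: int
    depth: np.ndarray  # per-base read depth
    read_ids: list


@dataclass
class AssemblyResult:
    contigs: list  # AssembledContig, length >= min_contig_len, >= 2 reads
    singletons: list  # unmerged single reads
    discarded_short: int  # multi-read contigs dropped by the length cutoff


class _Contig:
    __slots__ = ("cid", "arr", "counts", "read_ids", "alive")

    def __init__(self, cid: str, arr: np.ndarray, counts: np.ndarray, read_ids: list):
        self.cid = cid
        self.arr = arr
        self.counts = counts
        self.read_ids = read_ids
        self.alive = True


def _consensus(counts: np.ndarray) -> np.ndarray:
    return np.argmax(counts, axis=0).astype(np.uint8)


def _rc_counts(counts: np.ndarray) -> np.ndarray:
    # reverse columns; swap A<->T and C<->G rows
    return counts[[3, 2, 1, 0], ::-1].copy()


class GreedyAssembler:
    def __init__(
        self,
        min_overlap: int = 40,
        min_overlap_identity: float = 0.95,
        min_contig_len: int = 200,
        k: int = 12,
    ):
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        k = min(k, min_overlap)  # seeds must fit inside the shortest overlap
        self.min_overlap = min_overlap
        self.min_identity = min_overlap_identity
        self.min_contig_len = min_contig_len
        self.k = k
        self.contigs: dict[str, _Contig] = {}
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        self.heap: list = []
        self._counter = 0

    # ------------------------------------------------------------- indexing

    def _kmers(self, arr: np.ndarray):
        k = self.k
        for pos in range(arr.shape[0] - k + 1):
            kmer = arr[pos : pos + k]
            if (kmer == 4).any():
                continue
            yield kmer.tobytes(), pos

    def _add_to_index(self, cid: str, arr: np.ndarray) -> None:
        for key, pos in self._kmers(arr):
            self.index.setdefault(key, []).append((cid, pos))

    # ------------------------------------------------------- overlap finding

    def _candidates_for(self, cid: str) -> None:
        """Find verified overlaps of contig ``cid`` against indexed contigs."""
        contig = self.contigs[cid]
        for orient in ("+", "-"):
            arr = contig.arr if orient == "+" else _RC[contig.arr][::-1]
            hits: dict[tuple[str, int], None] = {}
            for key, qpos in self._kmers(arr):
                for oid, opos in self.index.get(key, ()):
                    other = self.contigs.get(oid)
                    if other is None or not other.alive or oid == cid:
                        continue
                    hits[(oid, opos - qpos)] = None
            for (oid, diag) in hits:
                self._verify_and_push(cid, orient, oid, diag)

    def _verify_and_push(self, cid: str, orient: str, oid: str, diag: int) -> None:
        """diag = offset of oriented-cid start within oid coordinates."""
        contig = self.contigs[cid]
        other = self.contigs[oid]
        q = contig.arr if orient == "+" else _RC[contig.arr][::-1]
        r = other.arr
        # place q at offset diag on r; if diag < 0, q extends left of r
        if diag >= 0:
            left_id, right_id, left_arr, right_arr, d = oid, cid, r, q, diag
            right_orient = orient
            left_orient = "+"
        else:
            left_id, right_id, left_arr, right_arr, d = cid, oid, q, r, -diag
            right_orient = "+"
            left_orient = orient
        o = min(left_arr.shape[0] - d, right_arr.shape[0])
        if o < self.min_overlap:
            return
        a = left_arr[d : d + o]
        b = right_arr[:o]
        mism = int(np.count_nonzero(a != b))
        identity = 1.0 - mism / o
        if identity < self.min_identity:
            return
        heapq.heappush(
            self.heap,
            (
                -o,
                -identity,
                left_id,
                right_id,
                left_orient,
                right_orient,
                d,
            ),
        )

    # --------------------------------------------------------------- merging

    def _merge(
        self, left_id: str, right_id: str, left_orient: str, right_orient: str, d: int
    ) -> str:
        left = self.contigs[left_id]
        right = self.contigs[right_id]
        lc = left.counts if left_orient == "+" else _rc_counts(left.counts)
        rc = right.counts if right_orient == "+" else _rc_counts(right.counts)
        new_len = max(lc.shape[1], d + rc.shape[1])
        counts = np.zeros((4, new_len), dtype=np.uint32)
        counts[:, : lc.shape[1]] += lc
        counts[:, d : d + rc.shape[1]] += rc
        left.alive = False
        right.alive = False
        cid = f"m{self._counter:06d}"
        self._counter += 1
        merged = _Contig(
            cid, _consensus(counts), counts, left.read_ids + right.read_ids
        )
        self.contigs[cid] = merged
        self._candidates_for(cid)
        self._add_to_index(cid, merged.arr)
        return cid

    # ------------------------------------------------------------------ run

    def assemble(self, reads: list[SequenceRead]) -> AssemblyResult:
        for i, read in enumerate(reads):
            arr = _encode(read.sequence.upper())
            counts = np.zeros((4, arr.shape[0]), dtype=np.uint32)
            valid = arr < 4
            counts[arr[valid], np.nonzero(valid)[0]] = 1
            cid = f"r{i:06d}"
            self.contigs[cid] = _Contig(cid, arr, counts, [read.read_id])
            self._candidates_for(cid)
            self._add_to_index(cid, arr)

        while self.heap:
            neg_o, _neg_ident, lid, rid, lor, ror, d = heapq.heappop(self.heap)
            lc = self.contigs.get(lid)
            rc = self.contigs.get(rid)
            if lc is None or rc is None or not (lc.alive and rc.alive):
                continue  # stale entry
            self._merge(lid, rid, lor, ror, d)

        contigs: list[AssembledContig] = []
        singletons: list[AssembledContig] = []
        discarded = 0
        n_out = 0
        for contig in self.contigs.values():
            if not contig.alive:
                continue
            seq = _decode(contig.arr)
            depth = contig.counts.sum(axis=0)
            rec = AssembledContig(
                contig_id="", sequence=seq, n_reads=len(contig.read_ids),
                depth=depth, read_ids=sorted(contig.read_ids),
            )
            if rec.n_reads == 1:
                rec.contig_id = f"singleton{len(singletons):05d}"
                singletons.append(rec)
            elif len(seq) >= self.min_contig_len:
                rec.contig_id = f"contig{n_out:05d}"
                n_out += 1
                contigs.append(rec)
            else:
                discarded += 1
        contigs.sort(key=lambda c: (-len(c.sequence), c.contig_id))
        for i, c in enumerate(contigs):
            c.contig_id = f"contig{i:05d}"
        return AssemblyResult(contigs=contigs, singletons=singletons,
                              discarded_short=discarded)


def greedy_assemble(
    reads: list[SequenceRead],
    min_overlap: int = 40,
    min_overlap_identity: float = 0.95,
    min_contig_len: int = 200,
) -> AssemblyResult:
    """Assemble reads; see :class:`GreedyAssembler` for the merge rule."""
    if not reads:
        return AssemblyResult(contigs=[], singletons=[], discarded_short=0)
    asm = GreedyAssembler(
        min_overlap=min_overlap,
        min_overlap_identity=min_overlap_identity,
        min_contig_len=min_contig_len,
    )
    return asm.assemble(reads)


@dataclass
class AssemblyStats:
    n_contigs: int
    n_reads_assembled: int
    pct_reads_assembled: float
    mean_length: float
    n50: int
    n75: int
    max_length: int
    total_length: int


def assembly_stats(
    contigs: list[AssembledContig], n_input_reads: int | None = None
) -> AssemblyStats:
    """Summary statistics; N50/N75 by the cumulative-length definition.

    N50 is the length of the contig at which the cumulative assembly length,
    walking contigs longest-first, first reaches half the total; N75
    analogously at three quarters.
    """
    if not contigs:
        return AssemblyStats(0, 0, 0.0, 0.0, 0, 0, 0, 0)
    lengths = sorted((len(c.sequence) for c in contigs), reverse=True)
    total = sum(lengths)
    n_reads = sum(c.n_reads for c in contigs)

    def n_stat(frac: float) -> int:
        cum = 0
        for L in lengths:
            cum += L
            if cum >= frac * total:
                return L
        return lengths[-1]

    return AssemblyStats(
        n_contigs=len(contigs),
        n_reads_assembled=n_reads,
        pct_reads_assembled=100.0 * n_reads / n_input_reads if n_input_reads else 0.0,
        mean_length=total / len(lengths),
        n50=n_stat(0.5),
        n75=n_stat(0.75),
        max_length=lengths[0],
        total_length=total,
    )
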