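"""Local sequence alignment with cost-based acceptance semantics.

The engine is a plain Smith-Waterman dynamic program over a score scheme
equivalent to cost-minimisation with mismatch cost 2 and insertion/deletion
cost 3 per base: a matching column scores +1, a mismatch -2, each gapped
base -3.  ``N`` never matches anything.  Tie-breaking is deterministic:
the best cell is the first encountered in row-major order, and traceback
prefers diagonal over read-gap over reference-gap moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

# base encoding: A=0 C=1 G=2 T=3, anything else (incl. N) = 4 and never matches
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0,C=1,G=2,T=3,other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap):
    n, m = q.shape[0], r.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == r[j - 1] and qi < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            p = 1
            up = H[i - 1, j] - gap
            if up > s:
                s = up
                p = 2
            left = H[i, j - 1] - gap
            if left > s:
                s = left
                p = 3
            if s <= 0:
                s = 0
                p = 0
            H[i, j] = s
            ptr[i, j] = p
            if s > best:
                best = s
                bi = i
                bj = j
    return H, ptr, best, bi, bj


@njit(cache=True)
def _sw_traceback(ptr, bi, bj):
    # returns reversed move codes (1 diag, 2 up, 3 left) and the start cell
    n_moves = 0
    i, j = bi, bj
    while ptr[i, j] != 0:
        p = ptr[i, j]
        n_moves += 1
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    moves = np.empty(n_moves, dtype=np.int8)
    i, j = bi, bj
    k = n_moves - 1
    while ptr[i, j] != 0:
        p = ptr[i, j]
        moves[k] = p
        k -= 1
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return moves, i, j


@dataclass
class LocalAlignment:
    """Best-scoring local alignment of a query against a reference segment."""

    score: int
    query_start: int  # 0-based, on query
    query_end: int  # half-open
    ref_start: int  # 0-based, on reference
    ref_end: int  # half-open
    operations: list = field(default_factory=list)  # [(op, length)]; op in M X I D
    n_matches: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def identity_over_query(self) -> float:
        """Matching columns as a fraction of aligned query bases."""
        if self.query_span == 0:
            return 0.0
        return self.n_matches / self.query_span

    def cigar(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.operations)


def smith_waterman(
    query: str | np.ndarray,
    ref: str | np.ndarray,
    match: int = 1,
    mismatch_cost: int = 2,
    gap_cost: int = 3,
) -> LocalAlignment | None:
    """Best local alignment of ``query`` against ``ref``; None if score 0."""
    q = encode(query) if isinstance(query, str) else query
    r = encode(ref) if isinstance(ref, str) else ref
    if q.size == 0 or r.size == 0:
        return None
    _H, ptr, best, bi, bj = _sw_fill(q, r, match, mismatch_cost, gap_cost)
    if best <= 0:
        return None
    moves, si, sj = _sw_traceback(ptr, bi, bj)
    ops: list[tuple[str, int]] = []
    n_match = 0
    qi, rj = si, sj
    for mv in moves:
        if mv == 1:
            op = "M" if (q[qi] == r[rj] and q[qi] < 4) else "X"
            if op == "M":
                n_match += 1
            qi += 1
            rj += 1
        elif mv == 2:
            op = "I"  # query base absent from reference
            qi += 1
        else:
            op = "D"  # reference base absent from query
            rj += 1
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return LocalAlignment(
        score=int(best),
        query_start=int(si),
        query_end=int(bi),
        ref_start=int(sj),
        ref_end=int(bj),
        operations=ops,
        n_matches=n_match,
    )
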