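"""Capture-target selection and probe tiling.

Targets are transcript contigs strictly longer than a length cutoff (750 bp
by default), plus any short sequences forced in by id (e.g. antimicrobial
peptide transcripts).  Probes are 120-mers tiled every 60 bp so interior
positions see exactly 2x probe coverage; a terminal probe anchored at the
contig 3' end guarantees full-length coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TargetContig:
    target_id: str
    sequence: str
    forced: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Probe:
    target_id: str
    start: int  # 0-based offset on the target
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


def select_targets(
    contigs: list[TargetContig],
    min_length: int = 750,
    force_include: set[str] | frozenset[str] = frozenset(),
) -> list[TargetContig]:
    """Keep contigs strictly longer than ``min_length`` plus forced ids.

    Selection is by strict inequality ("longer than"), order is preserved,
    and forced-in contigs are flagged.  Duplicate ids are an input error.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seen: set[str] = set()
    for c in contigs:
        if c.target_id in seen:
            raise ValueError(f"duplicate target id {c.target_id!r}")
        seen.add(c.target_id)
    selected = []
    for c in contigs:
        if c.length > min_length:
            selected.append(TargetContig(c.target_id, c.sequence, forced=False))
        elif c.target_id in force_include:
            selected.append(TargetContig(c.target_id, c.sequence, forced=True))
    return selected


def tile_probes(
    target: TargetContig, probe_len: int = 120, step: int = 60
) -> list[Probe]:
    """Tile probes at starts 0, step, 2*step, ... plus a terminal anchor.

    If the last regular start does not land exactly on length - probe_len,
    one extra probe anchored at the 3' end is appended so the probe union
    covers the whole contig.  Contigs shorter than ``probe_len`` yield no
    probes.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if not 1 <= step <= probe_len:
        raise ValueError("step must satisfy 1 <= step <= probe_len")
    L = target.length
    if L < probe_len:
        return []
    starts = list(range(0, L - probe_len + 1, step))
    terminal = L - probe_len
    if starts[-1] != terminal:
        starts.append(terminal)
    return [
        Probe(target.target_id, s, target.sequence[s : s + probe_len]) for s in starts
    ]


@dataclass
class ProbeSetSummary:
    n_targets: int
    n_probes: int
    total_target_bp: int
    total_target_mb: float
    depth_histogram: dict[int, int] = field(default_factory=dict)
    mean_interior_depth: float = 0.0


def probe_depth_vector(probes: list[Probe], target_length: int) -> np.ndarray:
    depth = np.zeros(target_length, dtype=np.int32)
    for p in probes:
        depth[p.start : p.end] += 1
    return depth


def mean_interior_probe_depth(
    probes: list[Probe], target_length: int, probe_len: int = 120
) -> float:
    """Mean per-base probe depth over positions >= probe_len from both ends."""
    if target_length < 2 * probe_len:
        return 0.0
    depth = probe_depth_vector(probes, target_length)
    interior = depth[probe_len : target_length - probe_len]
    return float(interior.mean()) if interior.size else 0.0


def probe_set_summary(
    probes: list[Probe],
    targets: list[TargetContig],
    probe_len: int = 120,
) -> ProbeSetSummary:
    """Aggregate probe-set bookkeeping: counts, target span, depth histogram."""
    known = {t.target_id: t for t in targets}
    for p in probes:
        if p.target_id not in known:
            raise ValueError(f"probe references unknown target {p.target_id!r}")
    total_bp = sum(t.length for t in targets)
    if not probes:
        return ProbeSetSummary(
            n_targets=len(targets),
            n_probes=0,
            total_target_bp=total_bp,
            total_target_mb=total_bp / 1e6,
        )
    by_target: dict[str, list[Probe]] = {}
    for p in probes:
        by_target.setdefault(p.target_id, []).append(p)
    hist: dict[int, int] = {}
    interior_sum = 0.0
    interior_n = 0
    for tid, plist in by_target.items():
        t = known[tid]
        depth = probe_depth_vector(plist, t.length)
        vals, counts = np.unique(depth, return_counts=True)
        for v, c in zip(vals, counts):
            hist[int(v)] = hist.get(int(v), 0) + int(c)
        if t.length >= 2 * probe_len:
            interior = depth[probe_len : t.length - probe_len]
            interior_sum += float(interior.sum())
            interior_n += interior.size
    return ProbeSetSummary(
        n_targets=len(targets),
        n_probes=len(probes),
        total_target_bp=total_bp,
        total_target_mb=total_bp / 1e6,
        depth_histogram=dict(sorted(hist.items())),
        mean_interior_depth=interior_sum / interior_n if interior_n else 0.0,
    )


def target_size_fraction(target_bp: float, genome_bp: float) -> float:
    """Captured target span as a percentage of the genome size."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return 100.0 * target_bp / genome_bp
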