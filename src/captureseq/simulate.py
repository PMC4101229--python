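"""Synthetic diploid genome, gene models, planted variants and simulated reads.

The generator emulates the study design that motivates the pipeline: a single
diploid individual of a species with no reference genome, a transcript
catalogue (exon concatenations), hybridisation capture that enriches genomic
fragments overlapping the probe-covered (exonic) regions, medium-length
single-end genomic reads with PCR clonal duplicates and adapter carry-over,
and short exon-only RNA-seq reads.  Every stochastic quantity is drawn from
one seeded NumPy generator, so a fixed seed gives byte-identical output.

Default study conditions: per-base heterozygous SNP rate 0.7% (the variation
frequency observed in the organism this emulates), clonal duplicate rate 36%,
genomic reads ~250 bp single-end with 0.5% substitution errors, capture
on-target depth 20x vs off-target 0.5x, RNA-seq 75 bp reads at 25x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRead

BASES = np.array(["A", "C", "G", "T"])

# the library adapter that may carry over into read 3' ends
DEFAULT_ADAPTER = "CCATCTCATCCCTGCGTGTCTCCGAC"


@dataclass
class GeneModel:
    """Exon/intron structure of one gene on one genomic contig.

    ``segments`` is an ordered list of (kind, start, end) with kind "exon" or
    "intron", 0-based half-open contig coordinates.  Segments must tile the
    gene span contiguously, starting and ending with an exon.
    """

    gene_id: str
    contig_id: str
    segments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.gene_id}: empty segment list")
        if self.segments[0][0] != "exon" or self.segments[-1][0] != "exon":
            raise ValueError(f"{self.gene_id}: first and last segments must be exons")
        for (k1, s1, e1), (k2, s2, e2) in zip(self.segments, self.segments[1:]):
            if e1 != s2:
                raise ValueError(f"{self.gene_id}: segments not contiguous")
            if k1 == k2:
                raise ValueError(f"{self.gene_id}: adjacent segments of same kind")
        for kind, s, e in self.segments:
            if e - s < 1:
                raise ValueError(f"{self.gene_id}: zero-length {kind}")

    @property
    def start(self) -> int:
        return self.segments[0][1]

    @property
    def end(self) -> int:
        return self.segments[-1][2]

    @property
    def span(self) -> int:
        return self.end - self.start

    def exons(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.segments if k == "exon"]

    def introns(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.segments if k == "intron"]

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons())


@dataclass
class SnpTruth:
    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str
    context: str  # exon | intron | intergenic


@dataclass
class TruthSet:
    """Machine-readable ground truth for parameter-recovery tests."""

    snp_truth: list[SnpTruth] = field(default_factory=list)
    intron_truth: list[tuple[str, int, int]] = field(default_factory=list)
    enrichment_factor_truth: dict[str, float] = field(default_factory=dict)
    clonal_duplicate_rate: float = 0.0


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    gene_models: list[GeneModel]
    transcripts: dict[str, str]
    microsats: dict[str, str]

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def _check_dist(name: str, dist: tuple[int, int]) -> None:
    lo, hi = dist
    if lo < 1 or hi < lo:
        raise ValueError(f"{name}: invalid length bounds {dist} (need 1 <= min <= max)")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def generate_genome(
    n_genes: int,
    exon_len_dist: tuple[int, int] = (150, 400),
    intron_len_dist: tuple[int, int] = (150, 600),
    intergenic_len_dist: tuple[int, int] = (300, 800),
    n_microsat: int = 5,
    seed: int = 0,
    exons_per_gene: tuple[int, int] = (1, 4),
) -> SyntheticGenome:
    """Build a toy genome with one gene (plus flanks) per contig.

    Transcripts are the exact exon concatenations of their gene models;
    microsatellite tracts (tandem repeats of 2-6 bp motifs) are planted in
    intergenic flanks and returned as a repeat library.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    _check_dist("exon_len_dist", exon_len_dist)
    _check_dist("intron_len_dist", intron_len_dist)
    _check_dist("intergenic_len_dist", intergenic_len_dist)
    _check_dist("exons_per_gene", exons_per_gene)

    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    models: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    flanks: list[tuple[str, int, int]] = []  # intergenic intervals for microsats

    for g in range(n_genes):
        contig_id = f"ctg{g:04d}"
        gene_id = f"gene{g:04d}"
        left = int(rng.integers(intergenic_len_dist[0], intergenic_len_dist[1] + 1))
        right = int(rng.integers(intergenic_len_dist[0], intergenic_len_dist[1] + 1))
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        segments: list[tuple[str, int, int]] = []
        pos = left
        for e in range(n_ex):
            elen = int(rng.integers(exon_len_dist[0], exon_len_dist[1] + 1))
            segments.append(("exon", pos, pos + elen))
            pos += elen
            if e < n_ex - 1:
                ilen = int(rng.integers(intron_len_dist[0], intron_len_dist[1] + 1))
                segments.append(("intron", pos, pos + ilen))
                pos += ilen
        seq = _random_seq(rng, pos + right)
        contigs[contig_id] = seq
        model = GeneModel(gene_id=gene_id, contig_id=contig_id, segments=segments)
        models.append(model)
        transcripts[gene_id] = "".join(seq[s:e] for s, e in model.exons())
        flanks.append((contig_id, 0, left))
        flanks.append((contig_id, pos, pos + right))

    microsats: dict[str, str] = {}
    for m in range(n_microsat):
        motif_len = int(rng.integers(2, 7))
        motif = _random_seq(rng, motif_len)
        n_copies = int(rng.integers(15, 40))
        tract = (motif * n_copies)[: motif_len * n_copies]
        # overwrite part of a random intergenic flank, keeping coordinates
        contig_id, fs, fe = flanks[int(rng.integers(0, len(flanks)))]
        if fe - fs < len(tract) + 2:
            tract = tract[: max(30, (fe - fs) - 2)]
        start = int(rng.integers(fs, fe - len(tract) + 1))
        seq = contigs[contig_id]
        contigs[contig_id] = seq[:start] + tract + seq[start + len(tract) :]
        microsats[f"msat{m:03d}"] = tract

    # rebuild transcripts in case a microsat landed near a gene (flanks only,
    # so exon sequence is untouched; this is a cheap consistency guarantee)
    for model in models:
        seq = contigs[model.contig_id]
        transcripts[model.gene_id] = "".join(seq[s:e] for s, e in model.exons())

    return SyntheticGenome(
        contigs=contigs, gene_models=models, transcripts=transcripts, microsats=microsats
    )


def intron_truth_from_models(models: list[GeneModel]) -> list[tuple[str, int, int]]:
    return [(m.contig_id, s, e) for m in models for s, e in m.introns()]


def _context_maps(models: list[GeneModel]) -> dict[str, list[tuple[int, int, str]]]:
    ctx: dict[str, list[tuple[int, int, str]]] = {}
    for m in models:
        ctx.setdefault(m.contig_id, []).extend(
            (s, e, k) for k, s, e in m.segments
        )
    return ctx


def plant_variants(
    genome: SyntheticGenome,
    snp_rate: float = 0.007,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], list[SnpTruth]]:
    """Plant heterozygous SNPs: each lands on exactly one of the two haplotypes.

    Returns (haplotype_1, haplotype_2, snp_truth) with context labelled from
    the gene models (exon / intron / intergenic).
    """
    if not 0.0 <= snp_rate <= 0.05:
        raise ValueError(f"snp_rate {snp_rate} outside [0, 0.05]")
    rng = np.random.default_rng(seed)
    ctx_map = _context_maps(genome.gene_models)
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    truth: list[SnpTruth] = []
    for contig_id, seq in genome.contigs.items():
        n = len(seq)
        n_snps = rng.binomial(n, snp_rate) if snp_rate > 0 else 0
        positions = sorted(rng.choice(n, size=n_snps, replace=False)) if n_snps else []
        h1 = list(seq)
        h2 = list(seq)
        segs = ctx_map.get(contig_id, [])
        for pos in positions:
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            target = h1 if rng.integers(0, 2) == 0 else h2
            target[pos] = alt
            context = "intergenic"
            for s, e, kind in segs:
                if s <= pos < e:
                    context = kind
                    break
            truth.append(SnpTruth(contig_id, int(pos), ref, alt, context))
        hap1[contig_id] = "".join(h1)
        hap2[contig_id] = "".join(h2)
    return hap1, hap2, truth


def exon_capture_intervals(
    models: list[GeneModel], selected_gene_ids: set[str] | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Probe-covered genomic intervals: the exons of the captured genes.

    Probes tile each selected transcript end to end, so on the genome the
    probe-complementary sequence is exactly the exonic intervals.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        if selected_gene_ids is not None and m.gene_id not in selected_gene_ids:
            continue
        intervals.setdefault(m.contig_id, []).extend(m.exons())
    return intervals


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, list[int]]:
    quals = [30] * len(seq)
    if error_rate <= 0:
        return seq, quals
    arr = list(seq)
    n_err = rng.binomial(len(seq), error_rate)
    if n_err:
        for pos in rng.choice(len(seq), size=n_err, replace=False):
            ref = arr[pos]
            arr[pos] = str(rng.choice([b for b in "ACGT" if b != ref]))
            quals[pos] = int(rng.integers(2, 16))
    return "".join(arr), quals


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def simulate_capture_reads(
    haplotypes: tuple[dict[str, str], dict[str, str]],
    capture_intervals: dict[str, list[tuple[int, int]]],
    on_target_depth: float = 20.0,
    off_target_depth: float = 0.5,
    read_len_dist: tuple[float, float] = (250.0, 50.0),
    error_rate: float = 0.005,
    dup_rate: float = 0.36,
    adapter: str = DEFAULT_ADAPTER,
    adapter_frac: float = 0.2,
    seed: int = 0,
    run_label: str = "RUN_1",
) -> tuple[list[SequenceRead], TruthSet]:
    """Simulate capture-enriched single-end genomic reads from both haplotypes.

    Reads overlapping a probe-covered interval are drawn at ``on_target_depth``
    fold, elsewhere at ``off_target_depth``; a ``dup_rate`` fraction of emitted
    reads are exact clonal copies of earlier reads; ``adapter_frac`` of reads
    carry the full adapter appended at the 3' end.
    """
    if on_target_depth < 0 or off_target_depth < 0:
        raise ValueError("depths must be >= 0")
    if not 0.0 <= dup_rate < 1.0:
        raise ValueError("dup_rate must be in [0, 1)")
    total_capture = sum(
        e - s for ivs in capture_intervals.values() for s, e in ivs
    )
    if on_target_depth > 0 and total_capture == 0:
        raise ValueError("on_target_depth > 0 requires a non-empty probe set")

    rng = np.random.default_rng(seed)
    hap1, hap2 = haplotypes
    mean_len, sd_len = read_len_dist
    genome_len = sum(len(s) for s in hap1.values())

    n_on = int(round(on_target_depth * total_capture / mean_len))
    n_off = int(round(off_target_depth * max(genome_len - total_capture, 0) / mean_len))
    n_total = n_on + n_off
    n_dup = int(round(dup_rate * n_total))
    n_fresh = n_total - n_dup

    # flatten capture intervals for length-weighted sampling
    flat = [
        (cid, s, e) for cid, ivs in capture_intervals.items() for s, e in ivs
    ]
    weights = np.array([e - s for _, s, e in flat], dtype=float)
    if weights.sum() > 0:
        weights = weights / weights.sum()
    contig_ids = list(hap1)
    contig_w = np.array([len(hap1[c]) for c in contig_ids], dtype=float)
    contig_w = contig_w / contig_w.sum()

    frac_on = n_on / n_total if n_total else 0.0
    fresh: list[SequenceRead] = []
    for i in range(n_fresh):
        length = int(np.clip(rng.normal(mean_len, sd_len), 60, 600))
        hap = hap1 if rng.integers(0, 2) == 0 else hap2
        if rng.random() < frac_on and flat:
            cid, s, e = flat[int(rng.choice(len(flat), p=weights))]
            lo = max(0, s - length + 1)
            hi = max(lo, e - 1)
            start = int(rng.integers(lo, hi + 1))
        else:
            cid = contig_ids[int(rng.choice(len(contig_ids), p=contig_w))]
            start = int(rng.integers(0, max(1, len(hap[cid]) - length + 1)))
        seq = hap[cid][start : start + length]
        if len(seq) < 60:
            seq = hap[cid][max(0, len(hap[cid]) - length) :]
        if rng.integers(0, 2) == 1:
            seq = _revcomp(seq)
        seq, quals = _apply_errors(rng, seq, error_rate)
        if adapter and rng.random() < adapter_frac:
            seq = seq + adapter
            quals = quals + [30] * len(adapter)
        fresh.append(
            SequenceRead(f"read{i:07d}", seq, quals, run_label=run_label)
        )

    reads = list(fresh)
    for j in range(n_dup):
        src = reads[int(rng.integers(0, len(reads)))]
        reads.append(
            SequenceRead(
                f"dup{j:07d}", src.sequence, list(src.qualities), run_label=run_label
            )
        )
    order = rng.permutation(len(reads))
    reads = [reads[k] for k in order]

    truth = TruthSet(clonal_duplicate_rate=dup_rate)
    return reads, truth


def simulate_rnaseq_reads(
    transcripts: dict[str, str],
    depth: float = 25.0,
    read_len: int = 75,
    error_rate: float = 0.005,
    seed: int = 0,
) -> list[SequenceRead]:
    """Short single-end reads drawn uniformly from transcript (exon) sequence."""
    if not transcripts:
        return []
    shortest = min(len(s) for s in transcripts.values())
    if read_len > shortest:
        raise ValueError(
            f"read_len {read_len} exceeds shortest transcript ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    reads: list[SequenceRead] = []
    i = 0
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        n_reads = int(round(depth * len(seq) / read_len))
        for _ in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_len + 1))
            sub = seq[start : start + read_len]
            if rng.integers(0, 2) == 1:
                sub = _revcomp(sub)
            sub, quals = _apply_errors(rng, sub, error_rate)
            reads.append(SequenceRead(f"rna{i:07d}", sub, quals, run_label="RNASEQ"))
            i += 1
    return reads


def measured_duplicate_fraction(reads: list[SequenceRead]) -> float:
    """Fraction of reads whose exact sequence was already seen (clonality)."""
    if not reads:
        return 0.0
    n_unique = len({r.sequence for r in reads})
    return (len(reads) - n_unique) / len(reads)
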