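"""End-to-end orchestration: simulate -> design -> qc -> map -> assemble ->
gene structure -> SNPs -> concordance, with a report bundle on disk.

Every stage's numbers are recomputed from the in-memory objects that are
also written to files, so the bundle carries no hidden state; all
randomness derives from the one root seed in the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger("captureseq")

from . import __version__
from .assemble import assembly_stats, greedy_assemble
from .config import PipelineConfig
from .genestruct import (
    align_contig_to_targets,
    call_segments,
    candidate_intron_contigs,
    classify_complete_introns,
    coverage_profile,
    intron_stats,
)
from .io import (
    read_fasta,
    read_fastq,
    write_bed,
    write_fasta,
    write_fastq,
    write_gff3,
    write_json,
    write_sam,
    write_vcf,
)
from .mapping import ReferenceIndex, enrichment_report, map_reads
from .probes import (
    TargetContig,
    probe_set_summary,
    select_targets,
    tile_probes,
)
from .qc import run_qc
from .simulate import (
    exon_capture_intervals,
    generate_genome,
    intron_truth_from_models,
    plant_variants,
    simulate_capture_reads,
    simulate_rnaseq_reads,
)
from .variants import build_pileup, call_snps, intersect_snp_sets, snp_frequency


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    probe_summary: object = None
    qc_report: object = None
    enrichment: list = field(default_factory=list)
    assembly: object = None
    intron_calls: list = field(default_factory=list)
    intron_summary: object = None
    genomic_snps: list = field(default_factory=list)
    transcriptomic_snps: list = field(default_factory=list)
    intersection: object = None
    truth: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, simulate: bool = True
) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config, outdir=out)
    sim = config.simulation
    log.info("pipeline start: seed=%d outdir=%s simulate=%s", config.seed, out, simulate)

    # ------------------------------------------------------------- simulate
    stage = "simulate"
    try:
        if simulate:
            genome = generate_genome(
                n_genes=sim.n_genes,
                exon_len_dist=sim.exon_len_dist,
                intron_len_dist=sim.intron_len_dist,
                intergenic_len_dist=sim.intergenic_len_dist,
                n_microsat=sim.n_microsat,
                seed=config.seed,
                exons_per_gene=sim.exons_per_gene,
            )
            hap1, hap2, snp_truth = plant_variants(
                genome, snp_rate=sim.snp_rate, seed=config.seed + 1
            )
            targets_all = genome.transcripts
            repeats = genome.microsats
            result.truth = {
                "snp_truth": snp_truth,
                "intron_truth": intron_truth_from_models(genome.gene_models),
                "dup_rate": sim.dup_rate,
                "gene_models": genome.gene_models,
                "genome": genome,
                "haplotypes": (hap1, hap2),
            }
            write_fasta(genome.contigs, out / "genome.fasta")
            write_fasta(targets_all, out / "transcripts.fasta")
            write_fasta(repeats, out / "microsats.fasta")
        else:
            paths = config.paths
            for label in ("targets_fasta", "reads_fastq"):
                value = getattr(paths, label)
                if value is None or not Path(value).exists():
                    raise FileNotFoundError(
                        f"required input {label} missing: {value!r}"
                    )
            targets_all = read_fasta(paths.targets_fasta)
            repeats = read_fasta(paths.repeats_fasta) if paths.repeats_fasta else {}
    except Exception as exc:  # noqa: BLE001 - stage-labelled abort
        raise StageError(stage, exc) from exc

    # --------------------------------------------------------------- design
    stage = "design"
    try:
        contigs = [TargetContig(tid, seq) for tid, seq in targets_all.items()]
        selected = select_targets(
            contigs,
            min_length=config.probe.min_target_length,
            force_include=set(config.probe.force_include),
        )
        probes = [
            p
            for t in selected
            for p in tile_probes(t, config.probe.probe_len, config.probe.step)
        ]
        result.probe_summary = probe_set_summary(probes, selected, config.probe.probe_len)
        selected_ids = {t.target_id for t in selected}
        write_fasta(
            {f"{p.target_id}:{p.start}": p.sequence for p in probes},
            out / "probes.fasta",
        )
        write_bed(
            [(p.target_id, p.start, p.end, f"probe{i}") for i, p in enumerate(probes)],
            out / "probes.bed",
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -------------------------------------------------------- simulate reads
    stage = "simulate_reads"
    try:
        if simulate:
            capture_iv = exon_capture_intervals(
                genome.gene_models, selected_gene_ids=selected_ids
            )
            reads, truthset = simulate_capture_reads(
                (hap1, hap2),
                capture_iv,
                on_target_depth=sim.on_target_depth,
                off_target_depth=sim.off_target_depth,
                read_len_dist=(sim.read_len_mean, sim.read_len_sd),
                error_rate=sim.error_rate,
                dup_rate=sim.dup_rate,
                adapter=sim.adapter,
                adapter_frac=sim.adapter_frac,
                seed=config.seed + 2,
            )
            transcripts_diploid = {}
            for m in genome.gene_models:
                if m.gene_id not in targets_all:
                    continue
                for hap_idx, hap in enumerate((hap1, hap2)):
                    seq = hap[m.contig_id]
                    transcripts_diploid[f"{m.gene_id}|h{hap_idx + 1}"] = "".join(
                        seq[s:e] for s, e in m.exons()
                    )
            rnaseq = simulate_rnaseq_reads(
                transcripts_diploid,
                depth=sim.rnaseq_depth / 2,  # per haplotype
                read_len=sim.rnaseq_read_len,
                error_rate=sim.rnaseq_error_rate,
                seed=config.seed + 3,
            )
            write_fastq(reads, out / "capture_reads.fastq")
            write_fastq(rnaseq, out / "rnaseq_reads.fastq")
        else:
            reads = read_fastq(config.paths.reads_fastq)
            rnaseq = (
                read_fastq(config.paths.rnaseq_fastq, run_label="RNASEQ")
                if config.paths.rnaseq_fastq
                else []
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------- qc
    stage = "qc"
    try:
        repeat_index = ReferenceIndex(repeats, k=config.mapping.seed_k) if repeats else None
        adapters = [sim.adapter] if simulate and sim.adapter else []
        hq_reads, qc_report = run_qc(
            reads,
            adapters=adapters,
            repeat_index=repeat_index,
            min_mean_q=config.qc.min_mean_q,
            quality_mode=config.qc.quality_mode,
            min_len=config.qc.min_len,
            max_n=config.qc.max_n,
            adapter_min_overlap=config.qc.adapter_min_overlap,
            adapter_max_mismatch_frac=config.qc.adapter_max_mismatch_frac,
        )
        result.qc_report = qc_report
        write_json(qc_report.to_dict(), out / "qc_report.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ map
    stage = "map"
    try:
        target_seqs = {t.target_id: t.sequence for t in selected}
        target_index = ReferenceIndex(target_seqs, k=config.mapping.seed_k)
        mapper_kw = dict(
            mismatch_cost=config.mapping.mismatch_cost,
            gap_cost=config.mapping.gap_cost,
            min_length_fraction=config.mapping.min_length_fraction,
            min_similarity=config.mapping.min_similarity,
        )
        drop_ambiguous = config.mapping.ambiguous == "drop"
        alignments = map_reads(
            hq_reads, target_index, drop_ambiguous=drop_ambiguous, **mapper_kw
        )
        runs = sorted({r.run_label for r in reads})
        reports = []
        for run in runs:
            run_hq = [r for r in hq_reads if r.run_label == run]
            run_ids = {r.read_id for r in run_hq}
            run_aln = [a for a in alignments if a.read_id in run_ids]
            reports.append(
                enrichment_report(
                    run,
                    sum(1 for r in reads if r.run_label == run),
                    run_hq,
                    run_aln,
                    target_seqs,
                )
            )
        if len(runs) > 1:
            reports.append(
                enrichment_report("combined", len(reads), hq_reads, alignments, target_seqs)
            )
        result.enrichment = reports
        write_sam(alignments, target_seqs, out / "target_mapping.sam")
        pd.DataFrame([r.to_dict() for r in reports]).to_csv(
            out / "enrichment_report.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------- assemble
    stage = "assemble"
    try:
        asm = greedy_assemble(
            hq_reads,
            min_overlap=config.assembly.min_overlap,
            min_overlap_identity=config.assembly.min_overlap_identity,
            min_contig_len=config.assembly.min_contig_len,
        )
        stats = assembly_stats(asm.contigs, n_input_reads=len(hq_reads))
        result.assembly = stats
        contig_seqs = {c.contig_id: c.sequence for c in asm.contigs}
        write_fasta(contig_seqs, out / "assembly.fasta")
        pd.DataFrame([vars(stats)]).to_csv(
            out / "assembly_stats.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ----------------------------------------------------------- genestruct
    stage = "genestruct"
    try:
        gs = config.genestruct
        contig_index = ReferenceIndex(contig_seqs, k=config.mapping.seed_k)
        rna_alignments = map_reads(rnaseq, contig_index, **mapper_kw) if rnaseq else []
        by_contig: dict[str, list] = {cid: [] for cid in contig_seqs}
        for a in rna_alignments:
            by_contig[a.ref_id].append(a)
        profiles = {
            cid: coverage_profile(alns, cid, len(contig_seqs[cid]))
            for cid, alns in by_contig.items()
        }
        segments = {
            cid: call_segments(p, min_gap=gs.min_gap, min_exon=gs.min_exon)
            for cid, p in profiles.items()
        }
        candidates = candidate_intron_contigs(profiles, min_divergence=gs.min_divergence)
        intron_calls = []
        hsps_by_contig = {}
        for cid in candidates:
            hsps = align_contig_to_targets(
                contig_seqs[cid],
                target_seqs,
                min_hsp_score=gs.min_hsp_score,
                min_hsp_identity=gs.min_hsp_identity,
            )
            hsps_by_contig[cid] = hsps
            intron_calls.extend(
                classify_complete_introns(
                    cid,
                    contig_seqs[cid],
                    hsps,
                    segments[cid],
                    subject_gap_tolerance=gs.subject_gap_tolerance,
                )
            )
        result.intron_calls = intron_calls
        result.intron_summary = intron_stats(intron_calls)
        gff = []
        for cid, segs in segments.items():
            for kind, s, e in segs:
                gff.append((cid, "captureseq", kind, s, e, {"ID": f"{cid}:{s}-{e}"}))
        for i, call in enumerate(intron_calls):
            if call.complete:
                gff.append(
                    (
                        call.contig_id,
                        "captureseq",
                        "complete_intron",
                        call.start,
                        call.end,
                        {"ID": f"intron{i}", "target": call.target_id,
                         "motif": call.splice_motif},
                    )
                )
        write_gff3(gff, out / "gene_structure.gff3")
        summ = result.intron_summary
        pd.DataFrame([vars(summ)]).to_csv(
            out / "intron_summary.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ----------------------------------------------------------------- snps
    stage = "snps"
    try:
        snp_cfg = config.snps
        genomic_aln = map_reads(hq_reads, contig_index, **mapper_kw)
        g_by_contig: dict[str, list] = {cid: [] for cid in contig_seqs}
        for a in genomic_aln:
            g_by_contig[a.ref_id].append(a)
        genomic_snps = []
        transcriptomic_snps = []
        for cid, seq in contig_seqs.items():
            segs = segments.get(cid)
            g_counts = build_pileup(g_by_contig[cid], cid, seq)
            genomic_snps.extend(
                call_snps(
                    g_counts, seq, cid,
                    min_depth=snp_cfg.min_depth,
                    min_alt_fraction=snp_cfg.min_alt_fraction,
                    segments=segs, source="genomic",
                )
            )
            t_counts = build_pileup(by_contig[cid], cid, seq)
            transcriptomic_snps.extend(
                call_snps(
                    t_counts, seq, cid,
                    min_depth=snp_cfg.min_depth,
                    min_alt_fraction=snp_cfg.min_alt_fraction,
                    segments=segs, source="transcriptomic",
                )
            )
        result.genomic_snps = genomic_snps
        result.transcriptomic_snps = transcriptomic_snps
        result.intersection = intersect_snp_sets(genomic_snps, transcriptomic_snps)
        contig_lengths = {cid: len(s) for cid, s in contig_seqs.items()}
        rows = []
        exon_mask = {
            cid: [(s, e) for kind, s, e in segs if kind == "exon"]
            for cid, segs in segments.items()
        }
        for label, snpset in (
            ("genomic", genomic_snps),
            ("transcriptomic", transcriptomic_snps),
            ("common", result.intersection.common),
        ):
            if contig_lengths:
                freq, _per, exon_frac = snp_frequency(snpset, contig_lengths, exon_mask)
            else:
                freq, exon_frac = 0.0, float("nan")
            rows.append(
                {
                    "source": label,
                    "total_snps": len(snpset),
                    "contigs_with_snps": len({s.contig_id for s in snpset}),
                    "snp_frequency_pct": freq,
                    "denominator_bp": sum(contig_lengths.values()),
                    "snps_in_exons_frac": exon_frac,
                    "transitions": sum(1 for s in snpset if s.snp_class == "transition"),
                    "transversions": sum(
                        1 for s in snpset if s.snp_class == "transversion"
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(out / "snp_summary.tsv", sep="\t", index=False)
        write_vcf(genomic_snps + transcriptomic_snps + result.intersection.common,
                  out / "snps.vcf", contigs=contig_seqs)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------- manifest
    manifest = {
        "captureseq_version": __version__,
        "seed": config.seed,
        "parameters": {
            "probe": vars(config.probe),
            "qc": vars(config.qc),
            "mapping": vars(config.mapping),
            "assembly": vars(config.assembly),
            "genestruct": vars(config.genestruct),
            "snps": vars(config.snps),
            "simulation": vars(config.simulation) if simulate else None,
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    write_json(manifest, out / "manifest.json")
    log.info(
        "pipeline done: %d contigs, %d complete introns, %d genomic SNPs",
        result.assembly.n_contigs,
        result.intron_summary.n_introns,
        len(result.genomic_snps),
    )
    return result
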