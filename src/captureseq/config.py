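"""Pipeline configuration: one YAML document, one root seed.

Defaults are the analysis thresholds the pipeline is built around (target
selection > 750 bp, 120-mer probes stepped 60 bp, mean quality > Q20, length
> 50 nt, at most 1 N, mapping costs 2/3/3 with 0.5/0.8 acceptance, SNPs at
>= 10x and >= 35% alternate fraction, intron candidacy at >= 250 bp
uncovered, intron gap >= 100 bp) plus the synthetic study conditions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import DEFAULT_ADAPTER


@dataclass
class SimulationConfig:
    n_genes: int = 8
    exon_len_dist: tuple[int, int] = (150, 400)
    intron_len_dist: tuple[int, int] = (150, 600)
    intergenic_len_dist: tuple[int, int] = (300, 800)
    exons_per_gene: tuple[int, int] = (1, 4)
    n_microsat: int = 4
    snp_rate: float = 0.007
    on_target_depth: float = 25.0
    off_target_depth: float = 0.5
    read_len_mean: float = 250.0
    read_len_sd: float = 50.0
    error_rate: float = 0.005
    dup_rate: float = 0.36
    adapter: str = DEFAULT_ADAPTER
    adapter_frac: float = 0.2
    rnaseq_depth: float = 25.0
    rnaseq_read_len: int = 75
    rnaseq_error_rate: float = 0.005


@dataclass
class ProbeConfig:
    min_target_length: int = 750
    probe_len: int = 120
    step: int = 60
    force_include: list = field(default_factory=list)


@dataclass
class QCConfig:
    min_mean_q: float = 20.0
    quality_mode: str = "mean"
    min_len: int = 50
    max_n: int = 1
    adapter_min_overlap: int = 8
    adapter_max_mismatch_frac: float = 0.1


@dataclass
class MappingConfig:
    seed_k: int = 13
    mismatch_cost: int = 2
    gap_cost: int = 3
    min_length_fraction: float = 0.5
    min_similarity: float = 0.8
    ambiguous: str = "assign"  # assign | drop


@dataclass
class AssemblyConfig:
    min_overlap: int = 40
    min_overlap_identity: float = 0.95
    min_contig_len: int = 200


@dataclass
class GeneStructConfig:
    min_gap: int = 100
    min_exon: int = 20
    min_divergence: int = 250
    min_hsp_score: int = 30
    min_hsp_identity: float = 0.8
    subject_gap_tolerance: int = 10


@dataclass
class SNPConfig:
    min_depth: int = 10
    min_alt_fraction: float = 0.35


@dataclass
class PathsConfig:
    targets_fasta: str | None = None
    reads_fastq: str | None = None
    rnaseq_fastq: str | None = None
    repeats_fasta: str | None = None
    qpcr_tsv: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    genestruct: GeneStructConfig = field(default_factory=GeneStructConfig)
    snps: SNPConfig = field(default_factory=SNPConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "simulation": SimulationConfig,
            "probe": ProbeConfig,
            "qc": QCConfig,
            "mapping": MappingConfig,
            "assembly": AssemblyConfig,
            "genestruct": GeneStructConfig,
            "snps": SNPConfig,
            "paths": PathsConfig,
        }
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for name, klass in sections.items():
            data = dict(raw.get(name, {}))
            for key, value in data.items():
                if isinstance(value, list) and key.endswith(("_dist", "per_gene")):
                    data[key] = tuple(value)
            kwargs[name] = klass(**data)
        return cls(**kwargs)
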