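"""qPCR enrichment-fold computation from Ct tables.

Fold enrichment between a raw and a capture-enriched DNA library is derived
from cycle-threshold differences: per matched dilution,
``fold = E ** (mean Ct_raw - mean Ct_enriched)`` with amplification
efficiency E (2 for perfect doubling); the assay-level fold is the geometric
mean across dilutions.  Depletion (fold < 1) is additionally reported in the
signed convention -1/fold, so a 867-fold depletion prints as -867.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean


@dataclass
class QPCRMeasurement:
    """Replicate Ct values for one assay, keyed by dilution and condition."""

    assay_id: str
    status: str  # "on-target" | "off-target"
    ct: dict[float, dict[str, list[float]]] = field(default_factory=dict)
    # ct[dilution]["raw"] and ct[dilution]["enriched"] are replicate lists

    def add(self, dilution: float, condition: str, value: float) -> None:
        if value <= 0:
            raise ValueError(f"{self.assay_id}: Ct must be positive, got {value}")
        self.ct.setdefault(dilution, {}).setdefault(condition, []).append(value)


@dataclass
class EnrichmentFold:
    assay_id: str
    fold: float  # E**dCt, geometric mean over dilutions
    signed_fold: float  # fold if >= 1 else -1/fold
    n_dilutions: int


def qpcr_enrichment_fold(
    measurement: QPCRMeasurement, amplification_efficiency: float = 2.0
) -> EnrichmentFold:
    """Geometric-mean fold enrichment across matched dilutions."""
    if amplification_efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    dilutions = sorted(measurement.ct)
    if not dilutions:
        raise ValueError(f"{measurement.assay_id}: no Ct data")
    log_folds = []
    for d in dilutions:
        conds = measurement.ct[d]
        if "raw" not in conds or "enriched" not in conds:
            raise ValueError(
                f"{measurement.assay_id}: dilution {d} lacks a matched "
                "raw/enriched Ct pair"
            )
        d_ct = mean(conds["raw"]) - mean(conds["enriched"])
        log_folds.append(d_ct)  # log base E_amp of the fold
    mean_log = mean(log_folds)
    fold = amplification_efficiency**mean_log
    signed = fold if fold >= 1.0 else -1.0 / fold
    return EnrichmentFold(
        assay_id=measurement.assay_id,
        fold=fold,
        signed_fold=signed,
        n_dilutions=len(dilutions),
    )


def read_qpcr_table(path: str | Path) -> list[QPCRMeasurement]:
    """Parse a TSV with columns assay_id, status, dilution, condition, ct."""
    assays: dict[str, QPCRMeasurement] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"assay_id", "status", "dilution", "condition", "ct"}
        missing = required - set(idx)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            aid = row[idx["assay_id"]]
            if aid not in assays:
                assays[aid] = QPCRMeasurement(aid, row[idx["status"]])
            assays[aid].add(
                float(row[idx["dilution"]]),
                row[idx["condition"]],
                float(row[idx["ct"]]),
            )
    return list(assays.values())
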