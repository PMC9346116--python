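"""Per-sample genomic biomarker computation.

Covers tumor mutational burden (TMB) with interval-arithmetic coding-length
denominators, the hypermutation flag, the copy-number based homologous
recombination deficiency composite (LOH-HRD + LST), microsatellite
instability classification, the germline-support flag, mutational-catalog
normalization and the multi-method viral-detection consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .io_formats import Segment, VariantSummary

__all__ = [
    "BiomarkerConfig",
    "ViralThresholds",
    "BiomarkerReport",
    "coding_length_mb",
    "compute_tmb",
    "flag_hypermutation",
    "loh_hrd_score",
    "lst_score",
    "classify_hrd",
    "classify_msi",
    "flag_germline",
    "normalize_catalog",
    "viral_consensus",
    "biomarker_report",
    "CODING_LENGTH_MB",
]

# Coding-sequence lengths (Mb) per sequencing platform: merged GENCODE v19
# CDS, intersected with the capture target for the exome kits.
CODING_LENGTH_MB = {
    "WGS": 35.334619,
    "WES_v5_UTR": 31.057260,
    "WES_v5": 30.894643,
}


@dataclass(frozen=True)
class ViralThresholds:
    """Per-method call thresholds for viral read detection."""

    kraken_reads_per_40m: float = 1.0
    kraken_genome_frac: float = 0.10
    pdip_reads_per_1m: float = 1.0
    arriba_genome_frac: float = 0.05
    arriba_min_bp: float = 100.0
    consensus_min_methods: int = 2


@dataclass(frozen=True)
class BiomarkerConfig:
    """Cutoffs of the biomarker calls; defaults are the clinical constants."""

    tmb_very_high_cutoff: float = 10.0  # mut/Mb
    hypermutation_cutoff: int = 100  # total non-silent SNVs + coding indels
    hrd_low_max: int = 10
    hrd_intermediate_max: int = 20
    msi_cutoff: float = 3.5
    germline_fraction: float = 1.0 / 30.0
    loh_min_mb: float = 15.0
    lst_min_segment_mb: float = 10.0
    lst_filter_below_mb: float = 3.0
    catalog_norm_wgs_mb: float = 2800.0
    catalog_norm_wes_mb: float = 30.0
    catalog_min_snvs: int = 50
    viral: ViralThresholds = field(default_factory=ViralThresholds)

    def __post_init__(self) -> None:
        if self.hrd_low_max >= self.hrd_intermediate_max:
            raise ValueError("hrd_low_max must be < hrd_intermediate_max")


@dataclass
class BiomarkerReport:
    sample_id: str
    tmb: float
    very_high_tmb: bool
    hypermutated: bool
    loh_hrd: Optional[int] = None
    lst: Optional[int] = None
    hrd_sum: Optional[int] = None
    hrd_class: Optional[str] = None
    msi_class: Optional[str] = None
    viruses_reported: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------


def coding_length_mb(
    cds_intervals: Optional[pr.PyRanges],
    capture_intervals: Optional[pr.PyRanges] = None,
) -> float:
    """Total merged coding-sequence length in megabases.

    CDS intervals are merged; when a capture target is supplied the
    merged union is intersected with the merged capture first (exome
    denominators).  Empty input yields 0.
    """
    if cds_intervals is None or len(cds_intervals) == 0:
        return 0.0
    merged = cds_intervals.merge()
    if capture_intervals is not None and len(capture_intervals) > 0:
        merged = merged.intersect(capture_intervals.merge())
        if len(merged) == 0:
            return 0.0
    total_bp = int((merged.End - merged.Start).sum())
    return total_bp / 1e6


def compute_tmb(
    variants: VariantSummary,
    length_mb: float,
    config: BiomarkerConfig = BiomarkerConfig(),
) -> tuple[float, bool]:
    """Mutations per Mb of coding sequence and the very-high flag (>= 10)."""
    if length_mb <= 0:
        raise ValueError(f"coding length must be positive, got {length_mb}")
    tmb = variants.total / length_mb
    return tmb, tmb >= config.tmb_very_high_cutoff


def flag_hypermutation(
    variants: VariantSummary, config: BiomarkerConfig = BiomarkerConfig()
) -> bool:
    """True when total non-silent SNVs + coding indels reaches the cutoff (100)."""
    return variants.total >= config.hypermutation_cutoff


# ---------------------------------------------------------------------------
# HRD composite
# ---------------------------------------------------------------------------


def _require_allele_specific(segments: Sequence[Segment]) -> None:
    for s in segments:
        if s.cn_major is None or s.cn_minor is None:
            raise ValueError(
                f"segment {s.chromosome}:{s.start}-{s.end} lacks allele-specific copy numbers"
            )


def loh_hrd_score(
    segments: Sequence[Segment],
    chromosome_lengths: Mapping[str, int],
    config: BiomarkerConfig = BiomarkerConfig(),
) -> int:
    """Count of long sub-chromosomal loss-of-heterozygosity regions.

    Maximal runs of adjacent LOH segments (minor copy number 0, major
    >= 1) are merged; a run counts when its merged length exceeds
    ``loh_min_mb`` and it does not span its entire chromosome.
    """
    _require_allele_specific(segments)
    score = 0
    for chrom, chrom_segs in _by_chromosome(segments):
        chrom_len = chromosome_lengths.get(chrom)
        run_start = run_end = None
        runs = []
        for s in chrom_segs:
            is_loh = s.cn_minor == 0 and s.cn_major >= 1
            if is_loh:
                if run_start is None:
                    run_start, run_end = s.start, s.end
                else:
                    run_end = s.end
            elif run_start is not None:
                runs.append((run_start, run_end))
                run_start = None
        if run_start is not None:
            runs.append((run_start, run_end))
        for start, end in runs:
            if (end - start) <= config.loh_min_mb * 1e6:
                continue
            if chrom_len is not None and start <= 0 and end >= chrom_len:
                continue  # whole-chromosome LOH does not count
            score += 1
    return score


def lst_score(
    segments: Sequence[Segment],
    chromosome_lengths: Optional[Mapping[str, int]] = None,
    config: BiomarkerConfig = BiomarkerConfig(),
) -> int:
    """Large-scale state transitions.

    Per chromosome, segments shorter than ``lst_filter_below_mb`` are
    discarded, adjacent segments with equal total copy number are merged,
    and each breakpoint whose two flanking segments are both at least
    ``lst_min_segment_mb`` long counts one transition.
    """
    _require_allele_specific(segments)
    score = 0
    for _, chrom_segs in _by_chromosome(segments):
        kept = [
            s for s in chrom_segs if s.length >= config.lst_filter_below_mb * 1e6
        ]
        merged: list[list] = []  # [start, end, total_cn]
        for s in kept:
            total = s.cn_major + s.cn_minor
            if merged and merged[-1][2] == total:
                merged[-1][1] = s.end
            else:
                merged.append([s.start, s.end, total])
        for left, right in zip(merged, merged[1:]):
            if (
                left[1] - left[0] >= config.lst_min_segment_mb * 1e6
                and right[1] - right[0] >= config.lst_min_segment_mb * 1e6
            ):
                score += 1
    return score


def _by_chromosome(segments: Sequence[Segment]):
    df = sorted(segments, key=lambda s: (s.chromosome, s.start))
    out: dict[str, list[Segment]] = {}
    for s in df:
        out.setdefault(s.chromosome, []).append(s)
    return out.items()


def classify_hrd(
    loh_hrd: int, lst: int, config: BiomarkerConfig = BiomarkerConfig()
) -> tuple[int, str]:
    """Unweighted LOH-HRD + LST sum and class: low <=10, intermediate 11-20, high >20."""
    if loh_hrd < 0 or lst < 0:
        raise ValueError("HRD components must be nonnegative")
    total = loh_hrd + lst
    if total <= config.hrd_low_max:
        return total, "low"
    if total <= config.hrd_intermediate_max:
        return total, "intermediate"
    return total, "high"


# ---------------------------------------------------------------------------
# MSI, germline flag, catalog normalization
# ---------------------------------------------------------------------------


def classify_msi(msi_score: float, config: BiomarkerConfig = BiomarkerConfig()) -> str:
    """MSI when the score strictly exceeds the cutoff (3.5), else MSS."""
    if msi_score < 0:
        raise ValueError(f"MSI score must be nonnegative, got {msi_score}")
    return "MSI" if msi_score > config.msi_cutoff else "MSS"


def flag_germline(
    control_alt_reads: int,
    control_depth: int,
    config: BiomarkerConfig = BiomarkerConfig(),
) -> bool:
    """Germline support: alternative-allele fraction in the control >= 1/30."""
    if control_alt_reads < 0 or control_depth < 0:
        raise ValueError("read counts must be nonnegative")
    if control_alt_reads > control_depth:
        raise ValueError("alt reads exceed depth")
    if control_depth == 0:
        return False
    return control_alt_reads / control_depth >= config.germline_fraction


def normalize_catalog(
    mutation_counts: Sequence[float],
    platform: str,
    config: BiomarkerConfig = BiomarkerConfig(),
) -> Optional[np.ndarray]:
    """Normalize a 96-channel mutational catalog by coding length.

    WGS catalogs are divided by 2800 Mb, WES by 30 Mb.  Samples with
    fewer than 50 SNVs are excluded (returns None).
    """
    counts = np.asarray(mutation_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"catalog must have 96 channels, got shape {counts.shape}")
    if counts.sum() < config.catalog_min_snvs:
        return None
    denom = config.catalog_norm_wgs_mb if platform == "WGS" else config.catalog_norm_wes_mb
    return counts / denom


# ---------------------------------------------------------------------------
# viral consensus
# ---------------------------------------------------------------------------

VIRAL_METHODS = frozenset({"kraken", "pdip", "arriba"})


def _method_passes(det: Mapping, thresholds: ViralThresholds) -> bool:
    method = det["method"]
    if method not in VIRAL_METHODS:
        raise ValueError(f"unknown viral detection method {method!r}")
    total = det.get("total_mapped_reads", 0)
    if method == "kraken":
        if total <= 0:
            raise ValueError("total_mapped_reads must be positive")
        return (
            det["viral_reads"] / total >= thresholds.kraken_reads_per_40m / 40e6
            and det.get("genome_frac_covered", 0.0) >= thresholds.kraken_genome_frac
        )
    if method == "pdip":
        if total <= 0:
            raise ValueError("total_mapped_reads must be positive")
        return det["viral_reads"] / total >= thresholds.pdip_reads_per_1m / 1e6
    # arriba: coverage must reach max(5% of genome, 100 bp)
    return (
        det.get("genome_frac_covered", 0.0) >= thresholds.arriba_genome_frac
        and det.get("bp_covered", 0.0) >= thresholds.arriba_min_bp
    )


def viral_consensus(
    detections: Sequence[Mapping],
    config: BiomarkerConfig = BiomarkerConfig(),
) -> pd.DataFrame:
    """Consensus virus calls over per-method detection summaries.

    Each detection record carries ``virus``, ``method`` and the method's
    evidence fields.  A virus is reported when at least
    ``consensus_min_methods`` methods pass their thresholds.  Returns a
    DataFrame indexed by virus with per-method pass flags and the
    ``reported`` column.
    """
    rows: dict[str, dict[str, bool]] = {}
    for det in detections:
        passes = _method_passes(det, config.viral)
        virus = det["virus"]
        entry = rows.setdefault(virus, {})
        entry[det["method"]] = entry.get(det["method"], False) or passes
    if not rows:
        return pd.DataFrame(columns=sorted(VIRAL_METHODS) + ["n_methods", "reported"])
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sorted(VIRAL_METHODS), fill_value=False
    )
    table = table.fillna(False).astype(bool)
    table["n_methods"] = table[sorted(VIRAL_METHODS)].sum(axis=1)
    table["reported"] = table["n_methods"] >= config.viral.consensus_min_methods
    table.index.name = "virus"
    return table.sort_index()


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def biomarker_report(
    variants: VariantSummary,
    segments: Optional[Sequence[Segment]] = None,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
    msi_score: Optional[float] = None,
    viral_detections: Optional[Sequence[Mapping]] = None,
    length_mb: Optional[float] = None,
    config: BiomarkerConfig = BiomarkerConfig(),
) -> BiomarkerReport:
    """Assemble the per-sample biomarker report from available inputs."""
    if length_mb is None:
        length_mb = CODING_LENGTH_MB[variants.platform]
    tmb, very_high = compute_tmb(variants, length_mb, config)
    report = BiomarkerReport(
        sample_id=variants.sample_id,
        tmb=tmb,
        very_high_tmb=very_high,
        hypermutated=flag_hypermutation(variants, config),
    )
    if segments is not None:
        loh = loh_hrd_score(segments, chromosome_lengths or {}, config)
        lst = lst_score(segments, chromosome_lengths, config)
        report.loh_hrd, report.lst = loh, lst
        report.hrd_sum, report.hrd_class = classify_hrd(loh, lst, config)
    if msi_score is not None:
        report.msi_class = classify_msi(msi_score, config)
    if viral_detections is not None:
        table = viral_consensus(viral_detections, config)
        report.viruses_reported = table.index[table["reported"]].tolist()
    return report
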