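"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Four generators emulate the inputs of the downstream stages: an
entity-labelled expression reference with planted marker genes and
optional liver-contamination mixing, a methylome reference with planted
entity-specific hypermethylated CpG sets, copy-number segment tables
produced by the purity/ploidy forward model at known truth, and therapy
timelines with exponential event times.  All generators are
deterministic under a fixed config and seed.

The generators emulate separation structure only — entity markers are
disjoint by construction and noise is independent per feature; they make
no attempt to mimic real TCGA signatures, batch effects or correlated
noise.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cna_fit import expected_ratio_baf
from .io_formats import (
    ExpressionProfile,
    MethylomeProfile,
    Segment,
    SurvivalRecord,
    TherapyLine,
)

__all__ = [
    "SyntheticConfig",
    "ExpressionCohort",
    "MethylomeCohort",
    "CnaTruth",
    "ClinicalCohort",
    "gen_expression_cohort",
    "gen_methylome_cohort",
    "gen_cna_truth",
    "gen_clinical",
]

_ENTITY_PALETTE = [
    "PAAD", "CHOL", "LUAD", "BRCA", "PRAD", "KIRC",
    "SKCM", "OV", "GBM", "UCEC", "HNSC", "THCA",
]

# approximate autosome lengths (bp), used to place synthetic segments
_CHROM_LENGTHS = {str(i): int(l * 1e6) for i, l in zip(range(1, 23), (
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
    135, 134, 115, 107, 102, 90, 81, 78, 59, 63, 48, 51,
))}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic cohorts.

    Defaults are sized for a desk-scale cohort: 6 entities x 20
    reference samples, 2000 genes and 5000 probes keep every stage well
    under a minute while preserving the separation structure the
    classifiers rely on.  Clinical hazards correspond to median
    progression times of roughly 2.9 (pre) and 7.8 (post) months and a
    median overall survival of about 22 months.
    """

    seed: int = 0
    # expression
    n_entities: int = 6
    samples_per_entity: int = 20
    n_genes: int = 2000
    markers_per_entity: int = 25
    marker_fpkm_mean: float = 50.0
    background_fpkm_mean: float = 1.0
    noise_cv: float = 0.2
    queries_per_entity: Optional[int] = None  # None = samples_per_entity
    liver_mix_fraction: float = 0.0
    n_liver_genes: int = 30
    include_liver_entity: bool = False
    # methylome
    n_probes: int = 5000
    cpgs_per_entity: int = 50
    beta_high: float = 0.8
    beta_low: float = 0.1
    missing_rate: float = 0.0
    snp_probe_fraction: float = 0.05
    # copy number
    n_segments: int = 40
    true_tcc: float = 0.6
    true_ploidy: float = 2.0
    cna_noise_sd: float = 0.0
    low_snp_fraction: float = 0.0
    # clinical
    n_patients: int = 20
    hazard_pre: float = math.log(2) / 2.9  # 1/months
    hazard_post: float = math.log(2) / 7.8
    hazard_os: float = math.log(2) / 22.1
    horizon_months: float = 72.0

    def __post_init__(self) -> None:
        if self.n_entities * self.markers_per_entity + self.n_liver_genes > self.n_genes:
            raise ValueError(
                f"marker budget ({self.n_entities}x{self.markers_per_entity} "
                f"+ {self.n_liver_genes} liver) exceeds {self.n_genes} genes"
            )
        if self.n_entities * self.cpgs_per_entity > self.n_probes:
            raise ValueError("CpG budget exceeds probe count")
        if self.beta_high <= self.beta_low:
            raise ValueError(f"beta_high ({self.beta_high}) must exceed beta_low ({self.beta_low})")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.liver_mix_fraction <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if not (0.15 <= self.true_tcc <= 1.0):
            raise ValueError(f"true_tcc {self.true_tcc} outside [0.15, 1.0]")
        if not (1.0 <= self.true_ploidy <= 6.5):
            raise ValueError(f"true_ploidy {self.true_ploidy} outside [1.0, 6.5]")
        if self.hazard_pre <= 0 or self.hazard_post <= 0 or self.hazard_os <= 0:
            raise ValueError("hazards must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    def entity_names(self) -> list[str]:
        names = list(_ENTITY_PALETTE)
        while len(names) < self.n_entities:
            names.append(f"ENT{len(names) + 1:02d}")
        return names[: self.n_entities]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal_around(rng, mean: np.ndarray, cv: float) -> np.ndarray:
    """Lognormal draws with the requested mean and coefficient of variation."""
    if cv == 0:
        return mean.astype(float).copy()
    sigma2 = math.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCohort:
    reference: list[ExpressionProfile]
    queries: list[ExpressionProfile]
    liver_genes: list[str]
    truth: dict[str, str]  # query sample_id -> true entity
    marker_genes: dict[str, list[str]]


def gen_expression_cohort(config: SyntheticConfig) -> ExpressionCohort:
    """Labelled FPKM reference plus queries with hidden true labels.

    Each entity owns a disjoint marker-gene block expressed around
    ``marker_fpkm_mean``; everything else sits at the background mean.
    Queries are fresh draws from the entity templates, convexly mixed
    with a liver profile (``x' = (1-f) x + f liver``) when
    ``liver_mix_fraction`` > 0, in which case they are tagged as liver
    biopsies.
    """
    rng = _rng(config, 1)
    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")
    entities = config.entity_names()

    marker_genes: dict[str, list[str]] = {}
    cursor = 0
    for ent in entities:
        marker_genes[ent] = list(genes[cursor : cursor + config.markers_per_entity])
        cursor += config.markers_per_entity
    liver_genes = list(genes[cursor : cursor + config.n_liver_genes])

    templates = {}
    for ent in entities:
        t = np.full(config.n_genes, config.background_fpkm_mean)
        t[genes.get_indexer(marker_genes[ent])] = config.marker_fpkm_mean
        templates[ent] = t
    liver_profile = np.full(config.n_genes, config.background_fpkm_mean)
    liver_profile[genes.get_indexer(liver_genes)] = config.marker_fpkm_mean

    reference = []
    for ent in entities:
        for j in range(config.samples_per_entity):
            vals = _lognormal_around(rng, templates[ent], config.noise_cv)
            reference.append(
                ExpressionProfile(f"REF_{ent}_{j:03d}", pd.Series(vals, index=genes), entity=ent)
            )
    if config.include_liver_entity:
        # liver-like tumors whose markers ARE the liver genes: these attract
        # liver-contaminated queries unless the liver mask is applied
        for j in range(config.samples_per_entity):
            vals = _lognormal_around(rng, liver_profile, config.noise_cv)
            reference.append(
                ExpressionProfile(f"REF_LIHC_{j:03d}", pd.Series(vals, index=genes), entity="LIHC")
            )

    n_queries = config.queries_per_entity
    if n_queries is None:
        n_queries = config.samples_per_entity
    queries, truth = [], {}
    liver_biopsy = config.liver_mix_fraction > 0
    for ent in entities:
        for j in range(n_queries):
            vals = _lognormal_around(rng, templates[ent], config.noise_cv)
            if liver_biopsy:
                f = config.liver_mix_fraction
                liver = _lognormal_around(rng, liver_profile, config.noise_cv)
                vals = (1 - f) * vals + f * liver
            sample_id = f"Q_{ent}_{j:03d}"
            queries.append(
                ExpressionProfile(
                    sample_id,
                    pd.Series(vals, index=genes),
                    biopsy_site="liver" if liver_biopsy else None,
                )
            )
            truth[sample_id] = ent
    return ExpressionCohort(reference, queries, liver_genes, truth, marker_genes)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


@dataclass
class MethylomeCohort:
    reference: pd.DataFrame  # probes x samples
    labels: pd.Series  # sample_id -> entity
    queries: pd.DataFrame
    truth: dict[str, str]
    snp_probes: list[str]
    platform_manifests: dict[str, list[str]]
    planted_cpgs: dict[str, list[str]]


def _beta_noise(rng, target: np.ndarray, cv: float) -> np.ndarray:
    """Beta-distributed draws with mean ``target`` and sd ~ cv * target."""
    if cv == 0:
        return target.astype(float).copy()
    var = np.minimum((cv * target) ** 2, 0.9 * target * (1 - target))
    var = np.maximum(var, 1e-12)
    k = target * (1 - target) / var - 1.0
    a = np.maximum(target * k, 1e-6)
    b = np.maximum((1 - target) * k, 1e-6)
    return rng.beta(a, b)


def gen_methylome_cohort(config: SyntheticConfig) -> MethylomeCohort:
    """Beta-value reference with planted entity-specific hypermethylated CpGs.

    Each entity's CpG block sits at ``beta_high`` in that entity's
    samples and ``beta_low`` elsewhere; remaining probes are uniformly
    at ``beta_low``.  Noise is Beta-distributed, missing cells are
    planted at ``missing_rate``, a disjoint probe subset is labelled as
    SNP-overlapping, and three manifests emulate the 850k/450k/27k
    platform intersection.
    """
    rng = _rng(config, 2)
    probes = pd.Index([f"cg{i:07d}" for i in range(config.n_probes)], name="probe_id")
    entities = config.entity_names()

    planted: dict[str, list[str]] = {}
    cursor = 0
    for ent in entities:
        planted[ent] = list(probes[cursor : cursor + config.cpgs_per_entity])
        cursor += config.cpgs_per_entity
    n_planted = cursor
    free = probes[n_planted:]

    n_snp = int(round(config.snp_probe_fraction * config.n_probes))
    snp_probes = list(rng.choice(free, size=min(n_snp, len(free)), replace=False))

    manifests = {"850k": list(probes)}
    droppable = free[~free.isin(snp_probes)]
    for name in ("450k", "27k"):
        drop = set(rng.choice(droppable, size=min(len(droppable) // 20, len(droppable)), replace=False))
        manifests[name] = [p for p in probes if p not in drop]

    def draw_samples(prefix: str, per_entity: int):
        cols, data, ents = [], [], []
        for ent in entities:
            target = np.full(config.n_probes, config.beta_low)
            target[probes.get_indexer(planted[ent])] = config.beta_high
            for j in range(per_entity):
                data.append(_beta_noise(rng, target, config.noise_cv))
                cols.append(f"{prefix}_{ent}_{j:03d}")
                ents.append(ent)
        frame = pd.DataFrame(np.column_stack(data), index=probes, columns=cols)
        return frame, pd.Series(ents, index=cols)

    reference, labels = draw_samples("REF", config.samples_per_entity)
    n_queries = config.queries_per_entity
    if n_queries is None:
        n_queries = config.samples_per_entity
    queries, q_labels = draw_samples("Q", n_queries)
    truth = q_labels.to_dict()

    if config.missing_rate > 0:
        def punch_holes(frame: pd.DataFrame) -> pd.DataFrame:
            mask = rng.random(frame.shape) < config.missing_rate
            # keep at least one observed value per probe
            mask[mask.all(axis=1), 0] = False
            return frame.mask(mask)

        reference = punch_holes(reference)
        queries = punch_holes(queries)

    return MethylomeCohort(
        reference, labels, queries, truth, snp_probes, manifests, planted
    )


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


@dataclass
class CnaTruth:
    segments: list[Segment]
    true_tcc: float
    true_ploidy: float
    chromosome_lengths: dict[str, int]


# allele-specific copy-number states sampled for synthetic segments
_CN_STATES = [(1, 1), (2, 1), (2, 0), (1, 0), (2, 2), (3, 1), (3, 2), (4, 2)]


def gen_cna_truth(config: SyntheticConfig) -> CnaTruth:
    """Segment table generated by the purity/ploidy forward model.

    Integer allele-specific copy numbers are drawn per segment; coverage
    ratio and BAF follow the admixture forward model at
    (``true_tcc``, ``true_ploidy``) exactly, with optional multiplicative
    coverage noise of relative sd ``cna_noise_sd``.  Heterozygous-SNP
    counts stay >= 20 unless ``low_snp_fraction`` deliberately plants
    under-covered segments for filter tests.
    """
    rng = _rng(config, 3)
    chroms = list(_CHROM_LENGTHS)
    segments = []
    for i in range(config.n_segments):
        chrom = chroms[i % len(chroms)]
        chrom_len = _CHROM_LENGTHS[chrom]
        length = int(rng.uniform(5e6, 40e6))
        start = int(rng.uniform(0, max(1, chrom_len - length)))
        # cycle through the state palette so every cohort carries diverse states
        major, minor = _CN_STATES[i % len(_CN_STATES)]
        ratio, baf = expected_ratio_baf(major + minor, minor, config.true_tcc, config.true_ploidy)
        if config.cna_noise_sd > 0:
            ratio *= 1.0 + rng.normal(0.0, config.cna_noise_sd)
        n_het = int(rng.integers(25, 200))
        if config.low_snp_fraction > 0 and rng.random() < config.low_snp_fraction:
            n_het = int(rng.integers(1, 20))
        segments.append(
            Segment(
                chromosome=chrom,
                start=start,
                end=start + length,
                coverage_ratio=max(ratio, 1e-6),
                baf=min(max(baf, 0.0), 0.5),
                n_het_snps=n_het,
                cn_major=major,
                cn_minor=minor,
            )
        )
    return CnaTruth(segments, config.true_tcc, config.true_ploidy, dict(_CHROM_LENGTHS))


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------


@dataclass
class ClinicalCohort:
    lines: list[TherapyLine]
    survival: list[SurvivalRecord]


_BASE_DATE = _dt.date(2015, 1, 1)


def _months_to_days(months: float) -> int:
    return max(1, int(round(months * 30.4375)))


def gen_clinical(config: SyntheticConfig) -> ClinicalCohort:
    """Therapy timelines with exponential progression times.

    Each patient carries a pre-recommendation line with
    Exponential(``hazard_pre``) time-to-progression followed by a
    recommended line with Exponential(``hazard_post``); lines running
    past ``horizon_months`` are censored there.  Overall-survival times
    are Exponential(``hazard_os``) with the same censoring horizon.
    """
    rng = _rng(config, 4)
    lines, survival = [], []
    horizon = config.horizon_months
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        start_pre = _BASE_DATE + _dt.timedelta(days=int(rng.integers(0, 365)))
        t_pre = rng.exponential(1.0 / config.hazard_pre)
        elapsed = t_pre
        if elapsed >= horizon:
            lines.append(
                TherapyLine(pid, "pre_mtb_last", start_pre,
                            start_pre + _dt.timedelta(days=_months_to_days(horizon)),
                            "censored")
            )
            continue  # no recommended line started within follow-up
        pre_end = start_pre + _dt.timedelta(days=_months_to_days(t_pre))
        lines.append(TherapyLine(pid, "pre_mtb_last", start_pre, pre_end, "progression"))

        t_post = rng.exponential(1.0 / config.hazard_post)
        if elapsed + t_post >= horizon:
            rec_end = start_pre + _dt.timedelta(days=_months_to_days(horizon))
            event = "censored"
        else:
            rec_end = pre_end + _dt.timedelta(days=_months_to_days(t_post))
            event = "progression"
        if rec_end > pre_end:
            lines.append(TherapyLine(pid, "recommended_first", pre_end, rec_end, event))

        t_os = rng.exponential(1.0 / config.hazard_os)
        survival.append(
            SurvivalRecord(pid, min(t_os, horizon), event=t_os < horizon)
        )
    return ClinicalCohort(lines, survival)
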