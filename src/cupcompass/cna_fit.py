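"""Tumor purity (TCC) and ploidy estimation by exhaustive grid search.

For a candidate tumor cell content ``tcc`` and ploidy, every segment's
coverage ratio and B-allele frequency imply real-valued total and minor
copy numbers.  In a correct solution those land on nonnegative integers,
so the fit objective is the length-weighted mean squared distance of the
implied copy numbers to their nearest integers, evaluated on an
exhaustive (tcc, ploidy) grid.  All local minima are returned ranked;
solutions at 100% tumor cell content are flagged unreliable because they
typically indicate a low-purity sample the model cannot anchor.

The forward model assumes a diploid (two-copy) admixed normal:

    coverage_ratio = (tcc * total + 2 (1 - tcc)) / (tcc * ploidy + 2 (1 - tcc))
    baf            = (tcc * minor + (1 - tcc)) / (tcc * total + 2 (1 - tcc))

with ``baf`` folded to [0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Segment

__all__ = [
    "PloidyPurityFit",
    "TCC_RANGE",
    "PLOIDY_RANGE",
    "MIN_HET_SNPS",
    "implied_copy_numbers",
    "expected_ratio_baf",
    "fit_ploidy_purity",
]

TCC_RANGE = (0.15, 1.0)
PLOIDY_RANGE = (1.0, 6.5)
MIN_HET_SNPS = 20
# minima with objectives within this relative band of the best are treated
# as indistinguishable and ordered by parsimony (lowest ploidy first)
PARSIMONY_BAND = 0.5


@dataclass
class PloidyPurityFit:
    tcc: float
    ploidy: float
    objective: float
    is_local_minimum: bool
    reliable: bool
    rank: int


def expected_ratio_baf(
    total_cn: float, minor_cn: float, tcc: float, ploidy: float
) -> tuple[float, float]:
    """Forward model: coverage ratio and folded BAF of a segment."""
    if not 0 < tcc <= 1:
        raise ValueError(f"tcc must be in (0, 1], got {tcc}")
    tumor_mass = tcc * total_cn + 2 * (1 - tcc)
    ratio = tumor_mass / (tcc * ploidy + 2 * (1 - tcc))
    baf = (tcc * minor_cn + (1 - tcc)) / tumor_mass
    return ratio, min(baf, 1 - baf)


def implied_copy_numbers(
    segment: Segment, tcc: float, ploidy: float
) -> tuple[float, float]:
    """Invert the forward model: real-valued (total, minor) copy numbers."""
    if tcc <= 0:
        raise ValueError(f"tcc must be positive, got {tcc}")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    contam = 2 * (1 - tcc)
    total = (segment.coverage_ratio * (tcc * ploidy + contam) - contam) / tcc
    minor = (segment.baf * (tcc * total + contam) - (1 - tcc)) / tcc
    return total, minor


def fit_ploidy_purity(
    segments: Sequence[Segment],
    tcc_step: float = 0.01,
    ploidy_step: float = 0.05,
    min_het_snps: int = MIN_HET_SNPS,
) -> list[PloidyPurityFit]:
    """Grid search over (tcc, ploidy); returns local minima ranked by objective.

    Segments with fewer than ``min_het_snps`` heterozygous SNPs are
    excluded.  A grid point is a local minimum when its objective is
    strictly smaller than all of its 8 grid neighbours; the global
    minimum is always included.  Fits with tcc = 1.0 are flagged
    ``reliable=False``.
    """
    kept = [s for s in segments if s.n_het_snps >= min_het_snps]
    if not kept:
        raise ValueError(
            f"no segment with >= {min_het_snps} heterozygous SNPs; cannot fit"
        )
    ratios = np.array([s.coverage_ratio for s in kept])
    bafs = np.array([s.baf for s in kept])
    lengths = np.array([s.length for s in kept], dtype=float)
    weights = lengths / lengths.sum()

    tccs = np.round(np.arange(TCC_RANGE[0], TCC_RANGE[1] + tcc_step / 2, tcc_step), 10)
    ploidies = np.round(
        np.arange(PLOIDY_RANGE[0], PLOIDY_RANGE[1] + ploidy_step / 2, ploidy_step), 10
    )
    t = tccs[:, None, None]  # grid axis 0
    p = ploidies[None, :, None]  # grid axis 1
    r = ratios[None, None, :]
    b = bafs[None, None, :]
    contam = 2 * (1 - t)
    total = (r * (t * p + contam) - contam) / t
    minor = (b * (t * total + contam) - (1 - t)) / t
    d_total = total - np.clip(np.round(total), 0, None)
    d_minor = minor - np.clip(np.round(minor), 0, None)
    objective = np.tensordot(d_total**2 + d_minor**2, weights, axes=([2], [0]))

    padded = np.pad(objective, 1, constant_values=np.inf)
    neighbour_min = np.full_like(objective, np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = padded[1 + di : 1 + di + objective.shape[0], 1 + dj : 1 + dj + objective.shape[1]]
            neighbour_min = np.minimum(neighbour_min, shifted)
    is_min = objective < neighbour_min

    # keep the global optimum even on flat plateaus where no strict minimum exists
    gi, gj = np.unravel_index(np.argmin(objective), objective.shape)
    is_min[gi, gj] = True

    ii, jj = np.where(is_min)
    fits = [
        PloidyPurityFit(
            tcc=float(tccs[i]),
            ploidy=float(ploidies[j]),
            objective=float(objective[i, j]),
            is_local_minimum=bool(objective[i, j] < neighbour_min[i, j]),
            reliable=bool(tccs[i] < TCC_RANGE[1]),
            rank=0,
        )
        for i, j in zip(ii, jj)
    ]
    # The grid objective carries an exact degeneracy: shifting every
    # segment's copy number by +2 at tcc' = tcc/(1-tcc), ploidy' = ploidy+2
    # reproduces identical ratios and BAFs, so minima come in families whose
    # objectives differ only by noise.  Among statistically indistinguishable
    # minima we prefer the most parsimonious (lowest-ploidy) solution, the
    # standard prior of purity/ploidy callers.
    best = min(f.objective for f in fits)
    band = best * (1.0 + PARSIMONY_BAND) + 1e-10
    fits.sort(
        key=lambda f: ((0, f.ploidy, f.tcc, f.objective) if f.objective <= band
                       else (1, f.objective, f.tcc, f.ploidy))
    )
    for rank, f in enumerate(fits, start=1):
        f.rank = rank
    return fits
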