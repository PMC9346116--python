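"""DNA-methylation nearest-neighbour tumor-entity classifier.

The classifier (i) drops probes overlapping known SNPs, (ii) keeps only
probes shared by the 850k, 450k and 27k array manifests, (iii) ranks the
survivors by beta-value variance across the reference cohort and keeps
the top K (default 5000), then predicts the entity of the reference
sample with the highest Spearman correlation to the query over the
selected probes.  Colorectal (COAD) and rectal (READ) adenocarcinomas
are reported as one merged basket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MethylomeProfile

__all__ = [
    "CpGSelection",
    "select_informative_probes",
    "impute_missing",
    "predict_entity_methylome",
    "embed_tsne",
    "merge_entity_basket",
]

MERGED_BASKETS = {"COAD": "COAD/READ", "READ": "COAD/READ"}


def merge_entity_basket(entity: str) -> str:
    """Map an entity label to its reporting basket (COAD/READ merged)."""
    return MERGED_BASKETS.get(entity, entity)


@dataclass
class CpGSelection:
    """Top-K most variant CpGs surviving the SNP and platform filters."""

    probe_ids: list[str]  # sorted by variance descending
    variances: pd.Series
    n_excluded_snp: int
    n_platform_common: int


def select_informative_probes(
    reference: pd.DataFrame,
    snp_probes: Iterable[str] = (),
    platform_manifests: Optional[Mapping[str, Iterable[str]]] = None,
    k: int = 5000,
) -> CpGSelection:
    """Select the K most variant CpGs across a probes x samples matrix.

    Variance is computed per probe over non-missing values (sample
    variance, n-1 denominator).  Ties are broken by probe id so the
    selection is deterministic.
    """
    snp_set = set(snp_probes)
    n_start = len(reference.index)
    kept = reference.index[~reference.index.isin(snp_set)]
    n_after_snp = len(kept)

    if platform_manifests:
        common = None
        for probes in platform_manifests.values():
            s = set(probes)
            common = s if common is None else common & s
        kept = kept[kept.isin(common)]
    n_common = len(kept)

    if n_common < k:
        raise ValueError(
            f"only {n_common} probes survive filtering (start {n_start}, "
            f"after SNP removal {n_after_snp}, after platform intersection "
            f"{n_common}); cannot select top {k}"
        )
    sub = reference.loc[kept]
    variances = sub.var(axis=1, ddof=1, skipna=True)
    order = pd.DataFrame({"var": variances, "probe": variances.index}).sort_values(
        by=["var", "probe"], ascending=[False, True], kind="mergesort"
    )
    top = order.head(k)
    return CpGSelection(
        probe_ids=top["probe"].tolist(),
        variances=variances.loc[top["probe"]],
        n_excluded_snp=n_start - n_after_snp,
        n_platform_common=n_common,
    )


def impute_missing(beta: pd.DataFrame, k_neighbours: int = 10) -> pd.DataFrame:
    """k-nearest-probe imputation of missing beta values.

    For each missing cell the k probes closest in Euclidean distance
    (over samples where both probes are observed) that carry a value in
    the target sample are averaged; results are clipped to [0, 1].
    Complete matrices are returned unchanged.
    """
    if not beta.isna().any().any():
        return beta.copy()
    values = beta.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if (~mask).all(axis=1).any():
        probe = beta.index[(~mask).all(axis=1)][0]
        raise ValueError(f"probe {probe} has no observed values; cannot impute")

    filled = np.where(mask, values, 0.0)
    n_probes = values.shape[0]
    # pairwise mean squared difference over shared observed samples
    shared = mask.astype(float) @ mask.astype(float).T
    cross = filled @ filled.T
    sq = (filled**2) @ mask.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (sq + sq.T - 2 * cross) / shared
    np.fill_diagonal(msd, np.inf)
    msd[shared == 0] = np.inf

    out = values.copy()
    for i in range(n_probes):
        miss_cols = np.where(~mask[i])[0]
        if len(miss_cols) == 0:
            continue
        order = np.argsort(msd[i], kind="stable")
        for j in miss_cols:
            donors = [p for p in order if mask[p, j] and np.isfinite(msd[i, p])]
            neigh = donors[:k_neighbours]
            if not neigh:
                raise ValueError(
                    f"no neighbour with data for probe {beta.index[i]}, sample {beta.columns[j]}"
                )
            out[i, j] = float(np.mean(values[neigh, j]))
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=beta.index, columns=beta.columns)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def predict_entity_methylome(
    query: MethylomeProfile,
    reference: pd.DataFrame,
    labels: Mapping[str, str],
    selection: CpGSelection,
    min_coverage: float = 0.8,
) -> tuple[str, pd.Series]:
    """Nearest-neighbour prediction by Spearman correlation over selected CpGs.

    Correlations use pairwise non-missing probes.  The query must cover
    at least ``min_coverage`` of the selected probes.  Returns the
    predicted basket label and the per-reference rho series (ties broken
    by sample id).
    """
    probes = pd.Index(selection.probe_ids)
    q = query.values.reindex(probes)
    coverage = q.notna().mean()
    if coverage < min_coverage:
        raise ValueError(
            f"query covers {coverage:.1%} of selected probes (< {min_coverage:.0%})"
        )
    sub = reference.reindex(probes)
    rhos = {}
    qv = q.to_numpy(dtype=float)
    for sample in sub.columns:
        rv = sub[sample].to_numpy(dtype=float)
        both = ~np.isnan(qv) & ~np.isnan(rv)
        if both.sum() < 3:
            rhos[sample] = np.nan
            continue
        rhos[sample] = _spearman(qv[both], rv[both])
    rho = pd.Series(rhos, name="spearman_rho")
    ranked = rho.reset_index().sort_values(
        by=["spearman_rho", "index"], ascending=[False, True], kind="mergesort"
    )
    best = ranked.iloc[0]["index"]
    return merge_entity_basket(labels[best]), rho


def embed_tsne(
    beta: pd.DataFrame,
    selection: Optional[CpGSelection] = None,
    perplexity: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of samples for visualization.

    Missing values are imputed first.  Perplexity is auto-reduced with a
    warning when the cohort is too small for the requested value.
    """
    from sklearn.manifold import TSNE

    sub = beta.loc[pd.Index(selection.probe_ids)] if selection is not None else beta
    sub = impute_missing(sub)
    x = sub.to_numpy(dtype=float).T  # samples x probes
    n = x.shape[0]
    eff_perplexity = perplexity
    if n <= 3 * perplexity:
        eff_perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} samples; reduced to {eff_perplexity:.1f}",
            UserWarning,
            stacklevel=2,
        )
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(x)
    return pd.DataFrame(coords, index=sub.columns, columns=["tsne1", "tsne2"])
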