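"""Pairwise-tournament transcriptome classifier for tumor tissue-of-origin.

A query expression profile is compared against every unordered pair of
reference samples.  Within a pair, each reference scores the fraction of
genes that are upregulated (FPKM > ``t_up``) in both the query and itself
while downregulated (FPKM < ``t_down``) in the other reference.  The
reference winning the most pairwise duels predicts the entity; references
labelled CUP are skipped when reading off the prediction.

Samples obtained by liver biopsy are prone to contamination by normal
liver tissue, so genes upregulated in normal liver can be masked from the
gene universe before the tournament.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionProfile, profiles_to_frame

__all__ = [
    "TournamentConfig",
    "TournamentResult",
    "build_gene_universe",
    "pair_similarity",
    "tournament_rank",
    "predict_entity_expression",
    "tune_thresholds",
    "classify_expression",
]


@dataclass(frozen=True)
class TournamentConfig:
    """Thresholds and options of the pairwise tournament.

    ``t_up``/``t_down`` are the FPKM cutoffs calling a gene up- or
    downregulated; values in between are neutral.  ``tie_award`` is the
    win fraction granted to each reference of a pair on an exact score
    tie.
    """

    t_up: float = 13.0
    t_down: float = 3.0
    liver_mask_enabled: bool = True
    tie_award: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.t_down < self.t_up):
            raise ValueError(f"require 0 < t_down < t_up, got ({self.t_down}, {self.t_up})")


@dataclass
class TournamentResult:
    """Ranked outcome of one query's tournament over a reference cohort."""

    table: pd.DataFrame  # index sample_id; columns wins, similarity_sum, rank, entity, is_cup
    predicted_entity: str
    winner_id: str
    cup_skipped: bool
    gene_universe_size: int

    @property
    def wins(self) -> pd.Series:
        return self.table["wins"]


def build_gene_universe(
    query: ExpressionProfile,
    reference: Sequence[ExpressionProfile],
    liver_gene_set: Iterable[str] = (),
    config: TournamentConfig = TournamentConfig(),
) -> pd.Index:
    """Ordered gene set shared by query and references, liver genes masked.

    The liver gene set is removed only when the query was obtained by
    liver biopsy and masking is enabled.
    """
    ref_genes = reference[0].values.index
    for p in reference[1:]:
        ref_genes = ref_genes.intersection(p.values.index)
    genes = query.values.index.intersection(ref_genes)
    if config.liver_mask_enabled and query.biopsy_site == "liver":
        genes = genes.difference(pd.Index(list(liver_gene_set)))
    if len(genes) == 0:
        raise ValueError("query and reference share no genes after masking")
    return genes.sort_values()


def pair_similarity(
    query: ExpressionProfile,
    ref_a: ExpressionProfile,
    ref_b: ExpressionProfile,
    genes: pd.Index,
    config: TournamentConfig = TournamentConfig(),
) -> tuple[float, float]:
    """Similarity scores of a reference pair against the query.

    ``score_a`` is the fraction of universe genes with query FPKM >
    ``t_up``, ``ref_a`` FPKM > ``t_up`` and ``ref_b`` FPKM < ``t_down``;
    ``score_b`` is symmetric.
    """
    if ref_a.sample_id == ref_b.sample_id:
        raise ValueError("pair_similarity requires two distinct references")
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    q = query.values.reindex(genes).to_numpy()
    a = ref_a.values.reindex(genes).to_numpy()
    b = ref_b.values.reindex(genes).to_numpy()
    q_up = q > config.t_up
    score_a = float(np.sum(q_up & (a > config.t_up) & (b < config.t_down))) / len(genes)
    score_b = float(np.sum(q_up & (b > config.t_up) & (a < config.t_down))) / len(genes)
    return score_a, score_b


def tournament_rank(
    query: ExpressionProfile,
    reference: Sequence[ExpressionProfile],
    liver_gene_set: Iterable[str] = (),
    config: TournamentConfig = TournamentConfig(),
) -> TournamentResult:
    """Run the full tournament and rank references by pairwise wins.

    Every unordered reference pair awards one win to the higher-scoring
    reference (``tie_award`` each on an exact tie).  Ranking ties are
    broken by the sum of a sample's own scores over all its pairs, then
    by sample id.  A single reference is ranked first with zero wins.
    """
    if len(reference) == 0:
        raise ValueError("reference cohort is empty")
    genes = build_gene_universe(query, reference, liver_gene_set, config)
    ref_matrix = profiles_to_frame(reference).reindex(genes).to_numpy().T  # n_ref x m
    q = query.values.reindex(genes).to_numpy()
    n = len(reference)
    m = len(genes)

    # Indicator precomputation: score[a, b] = |{g : q>t_up & a>t_up & b<t_down}| / m
    up_with_query = ((ref_matrix > config.t_up) & (q > config.t_up)).astype(np.float64)
    down = (ref_matrix < config.t_down).astype(np.float64)
    scores = up_with_query @ down.T / m
    np.fill_diagonal(scores, 0.0)

    wins = np.zeros(n)
    iu, ju = np.triu_indices(n, k=1)
    s_ab, s_ba = scores[iu, ju], scores[ju, iu]
    np.add.at(wins, iu, np.where(s_ab > s_ba, 1.0, np.where(s_ab == s_ba, config.tie_award, 0.0)))
    np.add.at(wins, ju, np.where(s_ba > s_ab, 1.0, np.where(s_ab == s_ba, config.tie_award, 0.0)))
    similarity_sum = scores.sum(axis=1)

    table = pd.DataFrame(
        {
            "wins": wins,
            "similarity_sum": similarity_sum,
            "entity": [p.entity for p in reference],
            "is_cup": [p.is_cup for p in reference],
        },
        index=pd.Index([p.sample_id for p in reference], name="sample_id"),
    )
    order = table.sort_values(
        by=["wins", "similarity_sum", "sample_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    table["rank"] = pd.Series(np.arange(1, n + 1), index=order)
    table = table.loc[order]

    predicted, winner_id, cup_skipped = _read_off_prediction(table)
    return TournamentResult(
        table=table,
        predicted_entity=predicted,
        winner_id=winner_id,
        cup_skipped=cup_skipped,
        gene_universe_size=m,
    )


def _read_off_prediction(table: pd.DataFrame) -> tuple[str, str, bool]:
    cup_skipped = False
    for sample_id, row in table.iterrows():
        if row["is_cup"]:
            cup_skipped = True
            continue
        return row["entity"], str(sample_id), cup_skipped
    raise ValueError("all reference samples are CUP; no predictable entity")


def predict_entity_expression(
    result: TournamentResult, reference_labels: Optional[Mapping[str, str]] = None
) -> str:
    """Entity of the top-ranked non-CUP reference of a tournament result."""
    table = result.table
    if reference_labels is not None:
        table = table.copy()
        table["entity"] = [reference_labels.get(s, e) for s, e in zip(table.index, table["entity"])]
    predicted, _, _ = _read_off_prediction(table)
    return predicted


def classify_expression(
    queries: Sequence[ExpressionProfile],
    reference: Sequence[ExpressionProfile],
    liver_gene_set: Iterable[str] = (),
    config: TournamentConfig = TournamentConfig(),
) -> pd.DataFrame:
    """Tournament prediction for every query; one row per query sample."""
    rows = []
    for q in queries:
        res = tournament_rank(q, reference, liver_gene_set, config)
        rows.append(
            {
                "sample_id": q.sample_id,
                "predicted_entity": res.predicted_entity,
                "winner_id": res.winner_id,
                "cup_skipped": res.cup_skipped,
                "gene_universe_size": res.gene_universe_size,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def tune_thresholds(
    reference: Sequence[ExpressionProfile],
    grid: Sequence[tuple[float, float]],
    n_folds: int = 10,
    seed: int = 0,
    liver_gene_set: Iterable[str] = (),
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Choose (t_up, t_down) by stratified cross-validated accuracy.

    Each grid point must satisfy ``t_down < t_up``.  Ties are broken
    toward the default (13, 3) when present, then toward the smallest
    ``t_up``.  Returns the winning pair and the per-point accuracy table.
    """
    if len(reference) < n_folds:
        raise ValueError(f"need >= {n_folds} samples for {n_folds}-fold CV, got {len(reference)}")
    for t_up, t_down in grid:
        if not t_down < t_up:
            raise ValueError(f"grid point ({t_up}, {t_down}) violates t_down < t_up")

    labels = np.array([p.entity for p in reference])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(reference)), labels))

    records = []
    for t_up, t_down in grid:
        cfg = TournamentConfig(t_up=t_up, t_down=t_down)
        correct = total = 0
        for _, test_idx in folds:
            test_set = set(test_idx)
            train = [p for i, p in enumerate(reference) if i not in test_set]
            for i in test_idx:
                res = tournament_rank(reference[i], train, liver_gene_set, cfg)
                correct += res.predicted_entity == reference[i].entity
                total += 1
        records.append({"t_up": t_up, "t_down": t_down, "cv_accuracy": correct / total})
    acc = pd.DataFrame(records)

    best_acc = acc["cv_accuracy"].max()
    top = acc[acc["cv_accuracy"] == best_acc]
    default = top[(top["t_up"] == 13.0) & (top["t_down"] == 3.0)]
    if len(default):
        row = default.iloc[0]
    else:
        row = top.sort_values(["t_up", "t_down"]).iloc[0]
    return (float(row["t_up"]), float(row["t_down"])), acc
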