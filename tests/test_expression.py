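"""Tournament classifier: duel scores, ranking, CUP-skip, threshold tuning."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from cupcompass import SyntheticConfig, gen_expression_cohort
from cupcompass.expression_entity import (
    TournamentConfig,
    build_gene_universe,
    classify_expression,
    pair_similarity,
    predict_entity_expression,
    tournament_rank,
    tune_thresholds,
)


# --------------------------------------------------------------------------
# independent oracle: naive loops over genes and pairs
# --------------------------------------------------------------------------


def naive_pair_score(q, a, b, t_up=13.0, t_down=3.0):
    hits = 0
    for g in q.index:
        if q[g] > t_up and a[g] > t_up and b[g] < t_down:
            hits += 1
    return hits / len(q.index)


def naive_tournament(query, reference, t_up=13.0, t_down=3.0):
    genes = query.values.index
    wins = {p.sample_id: 0.0 for p in reference}
    for a, b in itertools.combinations(reference, 2):
        sa = naive_pair_score(query.values[genes], a.values[genes], b.values[genes], t_up, t_down)
        sb = naive_pair_score(query.values[genes], b.values[genes], a.values[genes], t_up, t_down)
        if sa > sb:
            wins[a.sample_id] += 1
        elif sb > sa:
            wins[b.sample_id] += 1
        else:
            wins[a.sample_id] += 0.5
            wins[b.sample_id] += 0.5
    return wins


class TestPairSimilarity:
    def test_hand_example(self, profile_factory):
        q = profile_factory("q", [20, 20, 1, 1])
        a = profile_factory("a", [20, 20, 1, 1])
        b = profile_factory("b", [1, 1, 20, 20])
        genes = q.values.index
        assert pair_similarity(q, a, b, genes) == (0.5, 0.0)

    def test_identical_references_score_zero(self, profile_factory):
        q = profile_factory("q", [20, 20, 1, 1])
        a = profile_factory("a", [20, 1, 20, 1])
        b = profile_factory("b", [20, 1, 20, 1])
        assert pair_similarity(q, a, b, q.values.index) == (0.0, 0.0)

    def test_query_without_upregulation_scores_zero(self, profile_factory):
        q = profile_factory("q", [5, 5, 5, 5])
        a = profile_factory("a", [20, 20, 1, 1])
        b = profile_factory("b", [1, 1, 20, 20])
        assert pair_similarity(q, a, b, q.values.index) == (0.0, 0.0)

    def test_symmetric_under_swap(self, profile_factory):
        rng = np.random.default_rng(0)
        q = profile_factory("q", rng.uniform(0, 30, 20))
        a = profile_factory("a", rng.uniform(0, 30, 20))
        b = profile_factory("b", rng.uniform(0, 30, 20))
        sa, sb = pair_similarity(q, a, b, q.values.index)
        sb2, sa2 = pair_similarity(q, b, a, q.values.index)
        assert (sa, sb) == (sa2, sb2)

    def test_same_sample_pair_rejected(self, profile_factory):
        q = profile_factory("q", [1.0])
        a = profile_factory("a", [1.0])
        with pytest.raises(ValueError):
            pair_similarity(q, a, a, q.values.index)


class TestGeneUniverse:
    def test_liver_mask_only_for_liver_biopsy(self, profile_factory):
        refs = [profile_factory("r", [1, 1, 1, 1])]
        non_liver = profile_factory("q", [1, 1, 1, 1])
        masked = build_gene_universe(non_liver, refs, liver_gene_set={"g4"})
        assert list(masked) == ["g1", "g2", "g3", "g4"]
        liver = profile_factory("q", [1, 1, 1, 1], biopsy_site="liver")
        masked = build_gene_universe(liver, refs, liver_gene_set={"g4"})
        assert list(masked) == ["g1", "g2", "g3"]

    def test_disjoint_gene_sets_error(self, profile_factory):
        q = profile_factory("q", [1.0], genes=["gA"])
        r = profile_factory("r", [1.0], genes=["gB"])
        with pytest.raises(ValueError, match="no genes"):
            build_gene_universe(q, [r])


class TestTournament:
    def test_copy_of_query_wins(self, profile_factory):
        q = profile_factory("q", [20, 20, 1, 1])
        refs = [
            profile_factory("copy", [20, 20, 1, 1], entity="A"),
            profile_factory("r1", [1, 1, 20, 20], entity="B"),
            profile_factory("r2", [1, 1, 20, 20], entity="B"),
        ]
        res = tournament_rank(q, refs)
        assert res.winner_id == "copy"
        assert res.table.loc["copy", "wins"] == 2.0
        assert res.predicted_entity == "A"

    def test_matches_naive_oracle(self):
        """Optimized indicator path agrees exactly with the naive triple loop."""
        from cupcompass.io_formats import ExpressionProfile

        rng = np.random.default_rng(42)
        for trial in range(5):
            genes = [f"g{i}" for i in range(50)]
            refs = [
                ExpressionProfile(
                    f"s{j}", pd.Series(rng.uniform(0, 30, 50), index=genes), entity="E"
                )
                for j in range(8)
            ]
            q = ExpressionProfile("q", pd.Series(rng.uniform(0, 30, 50), index=genes))
            res = tournament_rank(q, refs)
            expected = naive_tournament(q, refs)
            for sid, w in expected.items():
                assert res.table.loc[sid, "wins"] == w

    def test_win_conservation(self, small_config):
        cohort = gen_expression_cohort(small_config)
        n = len(cohort.reference)
        res = tournament_rank(cohort.queries[0], cohort.reference)
        assert res.wins.sum() == pytest.approx(n * (n - 1) / 2)
        assert sorted(res.table["rank"]) == list(range(1, n + 1))

    def test_reference_order_invariance(self, small_config):
        cohort = gen_expression_cohort(small_config)
        refs = cohort.reference[:8]
        res1 = tournament_rank(cohort.queries[0], refs)
        res2 = tournament_rank(cohort.queries[0], refs[::-1])
        pd.testing.assert_frame_equal(
            res1.table.sort_index(), res2.table.sort_index()
        )
        assert res1.predicted_entity == res2.predicted_entity

    def test_single_reference(self, profile_factory):
        q = profile_factory("q", [20.0])
        res = tournament_rank(q, [profile_factory("r", [20.0], entity="A")])
        assert res.table.loc["r", "rank"] == 1
        assert res.table.loc["r", "wins"] == 0.0
        assert res.predicted_entity == "A"


class TestCupSkip:
    def _result(self, profile_factory, refs):
        q = profile_factory("q", [20, 20, 1, 1])
        return tournament_rank(q, refs)

    def test_rank1_non_cup(self, profile_factory):
        res = self._result(
            profile_factory,
            [
                profile_factory("r1", [20, 20, 1, 1], entity="PAAD"),
                profile_factory("r2", [1, 1, 20, 20], entity="CHOL"),
                profile_factory("r3", [1, 1, 20, 20], entity="CHOL"),
            ],
        )
        assert res.predicted_entity == "PAAD" and not res.cup_skipped

    def test_rank1_cup_skipped(self, profile_factory):
        res = self._result(
            profile_factory,
            [
                profile_factory("r1", [20, 20, 1, 1], entity="CUP", is_cup=True),
                profile_factory("r2", [20, 20, 1, 2], entity="CHOL"),
                profile_factory("r3", [1, 1, 20, 20], entity="SKCM"),
            ],
        )
        assert res.predicted_entity == "CHOL" and res.cup_skipped

    def test_all_cup_errors(self, profile_factory):
        refs = [
            profile_factory("r1", [20, 20, 1, 1], entity="CUP", is_cup=True),
            profile_factory("r2", [1, 1, 20, 20], entity="CUP", is_cup=True),
        ]
        q = profile_factory("q", [20, 20, 1, 1])
        with pytest.raises(ValueError, match="CUP"):
            tournament_rank(q, refs)


class TestAccuracyAndMasking:
    def test_zero_noise_accuracy_one(self, zero_noise_config):
        cohort = gen_expression_cohort(zero_noise_config)
        preds = classify_expression(cohort.queries, cohort.reference)
        truth = pd.Series(cohort.truth)
        assert (preds["predicted_entity"] == truth[preds.index]).all()

    def test_zero_noise_query_equals_template(self, zero_noise_config):
        cohort = gen_expression_cohort(zero_noise_config)
        by_entity = {}
        for p in cohort.reference:
            by_entity.setdefault(p.entity, p)
        for q in cohort.queries:
            template = by_entity[cohort.truth[q.sample_id]]
            assert np.array_equal(q.values.to_numpy(), template.values.to_numpy())

    def test_accuracy_monotone_in_noise(self, small_config):
        accs = []
        for cv in (0.0, 0.6, 1.8):
            cfg = dataclasses.replace(small_config, noise_cv=cv, seed=13)
            cohort = gen_expression_cohort(cfg)
            preds = classify_expression(cohort.queries, cohort.reference)
            truth = pd.Series(cohort.truth)
            accs.append((preds["predicted_entity"] == truth[preds.index]).mean())
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]

    def test_liver_masking_restores_accuracy(self, small_config):
        cfg = dataclasses.replace(
            small_config, liver_mix_fraction=0.5, noise_cv=0.1, include_liver_entity=True
        )
        cohort = gen_expression_cohort(cfg)
        truth = pd.Series(cohort.truth)
        masked = classify_expression(cohort.queries, cohort.reference, cohort.liver_genes)
        unmasked = classify_expression(
            cohort.queries, cohort.reference, cohort.liver_genes,
            TournamentConfig(liver_mask_enabled=False),
        )
        acc_masked = (masked["predicted_entity"] == truth[masked.index]).mean()
        acc_unmasked = (unmasked["predicted_entity"] == truth[unmasked.index]).mean()
        assert acc_masked >= acc_unmasked


class TestTuneThresholds:
    def test_singleton_grid(self, small_config):
        cohort = gen_expression_cohort(small_config)
        best, acc = tune_thresholds(cohort.reference, [(13.0, 3.0)], n_folds=5, seed=0)
        assert best == (13.0, 3.0)
        assert len(acc) == 1

    def test_tie_break_prefers_default(self, zero_noise_config):
        cohort = gen_expression_cohort(zero_noise_config)
        grid = [(40.0, 2.0), (13.0, 3.0), (20.0, 5.0)]
        best, acc = tune_thresholds(cohort.reference, grid, n_folds=5, seed=0)
        assert (acc["cv_accuracy"] == 1.0).all()  # separable by construction
        assert best == (13.0, 3.0)

    def test_invalid_grid_point_rejected(self, small_config):
        cohort = gen_expression_cohort(small_config)
        with pytest.raises(ValueError, match="t_down < t_up"):
            tune_thresholds(cohort.reference, [(3.0, 13.0)], n_folds=5)

    def test_too_few_samples(self, profile_factory):
        refs = [profile_factory(f"r{i}", [1.0], entity="A") for i in range(3)]
        with pytest.raises(ValueError, match="samples"):
            tune_thresholds(refs, [(13.0, 3.0)], n_folds=10)
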