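"""Type-constrained filtered ranking, MRR, baselines and diagnostics."""

import numpy as np
import pytest

from kgfilter.kg_core import KnowledgeGraph
from kgfilter.evaluation import (
    RankResult,
    candidates,
    case_study_ranks,
    evaluate_task,
    filtered_rank,
    mrr,
    random_baseline,
    score_distribution_diagnostic,
)
from kgfilter.kge_models import EmbeddingModel
from kgfilter.preprocess import add_inverses_to_bundle, make_holdout_splits

from oracles import brute_rank


def indicator_model(entities, relations, score_pairs, dim=None):
    """DistMult model with basis-vector tails and indicator heads.

    With all-ones relation vectors, score(h, r, t_i) equals the weight
    this head assigns to tail i, so arbitrary per-head score tables can
    be realized exactly.
    """
    tails = sorted({t for (_, t) in score_pairs})
    dim = dim or len(tails)
    eidx = {e: i for i, e in enumerate(entities)}
    emb = np.zeros((len(entities), dim))
    for j, t in enumerate(tails):
        emb[eidx[t], j] = 1.0
    for (h, t), v in score_pairs.items():
        emb[eidx[h], tails.index(t)] = v
    return EmbeddingModel(
        scorer="distmult", dimension=dim, entity_index=eidx,
        relation_index={r: i for i, r in enumerate(relations)},
        entity_emb=emb, relation_emb=np.ones((len(relations), dim)),
    )


def four_disease_kg():
    types = {"c1": "Compound", "d1": "Disease", "d2": "Disease",
             "d3": "Disease", "d4": "Disease"}
    triples = [("c1", "treats", "d1"), ("c1", "treats", "d2"),
               ("d3", "affects", "c1"), ("d4", "affects", "c1")]
    return KnowledgeGraph(triples, types)


class TestCandidates:
    def test_single_disease_gives_empty_set(self):
        kg = KnowledgeGraph(
            [("c", "treats", "d")], {"c": "Compound", "d": "Disease"}
        )
        assert candidates(kg, ("c", "treats", "d")) == set()

    def test_observed_tails_filtered(self):
        kg = four_disease_kg()
        cands = candidates(kg, ("c1", "treats", "d1"))
        # d1 is the true tail, d2 is observed: d3 and d4 remain
        assert cands == {"d3", "d4"}

    def test_type_constraint(self):
        kg = four_disease_kg()
        assert all(
            kg.type_of(e) == "Disease"
            for e in candidates(kg, ("c1", "treats", "d1"))
        )

    def test_evaluable_intersection(self):
        kg = four_disease_kg()
        cands = candidates(kg, ("c1", "treats", "d1"), evaluable={"d3"})
        assert cands == {"d3"}


class TestFilteredRank:
    def test_top_scoring_true_tail_ranks_first(self):
        model = indicator_model(
            ["c", "d1", "d2", "d3"], ["treats"],
            {("c", "d1"): 9.0, ("c", "d2"): 1.0, ("c", "d3"): 2.0},
        )
        r = filtered_rank(model, ("c", "treats", "d1"), {"d2", "d3"})
        assert r.rank == 1 and r.n_candidates == 2

    def test_all_tied_scores_take_midrank(self):
        model = indicator_model(
            ["c", "d0", "d1", "d2", "d3", "d4"], ["treats"],
            {("c", f"d{i}"): 5.0 for i in range(5)},
        )
        r = filtered_rank(model, ("c", "treats", "d0"), {f"d{i}" for i in range(1, 5)})
        assert r.rank == 3  # midpoint of 1..5, rounded up

    def test_agrees_with_brute_force_on_toy(self):
        rng = np.random.default_rng(8)
        table = {("c", f"d{i}"): float(rng.normal()) for i in range(5)}
        model = indicator_model(["c"] + [f"d{i}" for i in range(5)], ["treats"], table)
        cands = {f"d{i}" for i in range(1, 5)}
        ours = filtered_rank(model, ("c", "treats", "d0"), cands).rank
        brute = brute_rank(table[("c", "d0")],
                           [table[("c", f"d{i}")] for i in range(1, 5)])
        assert ours == brute

    def test_adding_observed_triple_never_worsens_rank(self):
        """Filtered setting: removing a strong competitor from the
        candidate pool can only improve the true tail's rank."""
        rng = np.random.default_rng(1)
        table = {("c", f"d{i}"): float(rng.normal()) for i in range(6)}
        model = indicator_model(["c"] + [f"d{i}" for i in range(6)], ["treats"], table)
        full = {f"d{i}" for i in range(1, 6)}
        before = filtered_rank(model, ("c", "treats", "d0"), full).rank
        after = filtered_rank(model, ("c", "treats", "d0"), full - {"d1"}).rank
        assert after <= before


class TestMRR:
    def test_all_rank_one(self):
        ranks = [RankResult(("a", "r", "b"), 1, 5)] * 4
        assert mrr(ranks) == 1.0

    def test_small_examples(self):
        def rr(*rs):
            return [RankResult(("a", "r", "b"), k, 9) for k in rs]

        assert mrr(rr(1, 2)) == pytest.approx(0.75)
        assert mrr(rr(1, 2, 3, 4)) == pytest.approx(25 / 48)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mrr([])


class TestEvaluateTask:
    def make_bundle_and_kg(self):
        types = {f"c{i}": "Compound" for i in range(3)}
        types.update({f"d{i}": "Disease" for i in range(4)})
        triples = [("c0", "treats", "d0"), ("c1", "treats", "d1"),
                   ("c2", "treats", "d2"), ("c0", "treats", "d3"),
                   ("c1", "treats", "d2")]
        kg = KnowledgeGraph(triples, types)
        bundle = make_holdout_splits(kg, "treats", 0.2, 0.2, seed=0)
        return kg, add_inverses_to_bundle(bundle)

    def test_perfect_oracle_scores_mrr_one(self):
        kg, bundle = self.make_bundle_and_kg()
        pairs = {(h, t) for h, r, t in kg.triples}
        table = {}
        for c in kg.entities_of_type("Compound"):
            for d in kg.entities_of_type("Disease"):
                v = 1.0 if (c, d) in pairs else 0.0
                table[(c, d)] = v
                table[(d, c)] = v
        model = indicator_model(sorted(kg.entities), ["treats", "treats_inv"], table)
        out = evaluate_task(model, kg, bundle, "validation")
        assert out["mrr"] == 1.0

    def test_query_count_covers_both_directions(self):
        kg, bundle = self.make_bundle_and_kg()
        model = indicator_model(sorted(kg.entities), ["treats", "treats_inv"],
                                {("c0", "d0"): 1.0})
        out = evaluate_task(model, kg, bundle, "validation")
        n_targets = sum(1 for t in bundle.validation if t[1] == "treats")
        assert out["n_queries"] == 2 * n_targets

    def test_missing_split_raises(self):
        kg, bundle = self.make_bundle_and_kg()
        bundle.test = set()
        model = indicator_model(sorted(kg.entities), ["treats", "treats_inv"], {})
        with pytest.raises(Exception):
            evaluate_task(model, kg, bundle, "test")


class TestRandomBaseline:
    def test_single_candidate_rows_score_one(self):
        table = {("c0", "d0"): 0.3, ("c1", "d1"): 0.9}
        truth = {("c0", "d0"), ("c1", "d1")}
        assert random_baseline(table, truth, n_rep=5) == 1.0

    def test_four_candidate_rows_converge_to_25_over_48(self):
        """Exhaustive-enumeration oracle: with one true pair per 4-column
        row the rank is uniform on {1..4}, so E[MRR] = H_4/4 = 25/48."""
        rng = np.random.default_rng(0)
        table = {
            (f"c{i}", f"d{j}"): float(rng.normal())
            for i in range(5) for j in range(4)
        }
        truth = {(f"c{i}", f"d{i % 4}") for i in range(5)}
        got = random_baseline(table, truth, n_rep=100,
                              rng=np.random.default_rng(123))
        # per-query var of 1/rank: E[1/r^2] - (25/48)^2
        var_q = (1 + 1 / 4 + 1 / 9 + 1 / 16) / 4 - (25 / 48) ** 2
        se = np.sqrt(var_q / 5 / 100)
        assert abs(got - 25 / 48) < 3 * se

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        table = {(f"c{i}", f"d{j}"): float(rng.normal())
                 for i in range(3) for j in range(4)}
        truth = {("c0", "d1"), ("c1", "d2"), ("c2", "d0")}
        a = random_baseline(table, truth, n_rep=20, rng=np.random.default_rng(9))
        squashed = {k: float(np.tanh(v)) for k, v in table.items()}
        b = random_baseline(squashed, truth, n_rep=20, rng=np.random.default_rng(9))
        assert a == pytest.approx(b)


class TestDiagnostic:
    def trained_toy(self):
        from kgfilter.kge_models import TrainConfig, train
        from test_kge_models import tiny_bundle

        kg, bundle = tiny_bundle(seed=6)
        model, _ = train("distmult", bundle,
                         TrainConfig(dimension=8, epochs_max=10, seed=3, min_epochs=10))
        return model, bundle

    def test_reproducible_given_seed(self):
        model, bundle = self.trained_toy()
        kwargs = dict(n_samples=1000, batch_size=100)
        d1 = score_distribution_diagnostic(model, bundle.train,
                                           rng=np.random.default_rng(4), **kwargs)
        d2 = score_distribution_diagnostic(model, bundle.train,
                                           rng=np.random.default_rng(4), **kwargs)
        assert np.array_equal(d1.positive_scores, d2.positive_scores)
        assert d1.divergence == d2.divergence

    def test_scores_scaled_to_unit_interval(self):
        model, bundle = self.trained_toy()
        d = score_distribution_diagnostic(model, bundle.train, n_samples=2000,
                                          batch_size=200,
                                          rng=np.random.default_rng(0))
        for arr in (d.positive_scores, d.negative_scores):
            assert arr.min() >= 0.0 and arr.max() <= 1.0
        assert d.divergence >= 0.0

    def test_constant_model_gives_zero_divergence(self):
        """All scores equal -> every batch degenerates to 0.5 -> the two
        histograms coincide and the divergence vanishes."""
        ents = [f"e{i}" for i in range(6)]
        model = EmbeddingModel(
            scorer="distmult", dimension=4,
            entity_index={e: i for i, e in enumerate(ents)},
            relation_index={"r": 0},
            entity_emb=np.zeros((6, 4)), relation_emb=np.zeros((1, 4)),
        )
        triples = {(ents[i], "r", ents[i + 1]) for i in range(5)}
        d = score_distribution_diagnostic(model, triples, n_samples=500,
                                          batch_size=100,
                                          rng=np.random.default_rng(1))
        assert d.divergence == pytest.approx(0.0)


class TestCaseStudy:
    def test_oracle_favoured_compound_ranks_first(self):
        types = {"dis": "Disease", "x": "Compound", "y": "Compound", "z": "Compound"}
        kg = KnowledgeGraph(
            [("x", "links", "dis"), ("y", "links", "dis"), ("z", "links", "dis")],
            types,
        )
        model = indicator_model(
            ["dis", "x", "y", "z"], ["treats_inv"],
            {("dis", "x"): 5.0, ("dis", "y"): 1.0, ("dis", "z"): 0.5},
        )
        out = case_study_ranks(model, ["dis"], kg, ["x", "y"])
        assert out["ranks"]["dis"]["x"] == 1
        assert out["expected_median_rank"] == 1  # floor(3/2)

    def test_mean_rank_is_arithmetic_mean(self):
        types = {"d1": "Disease", "d2": "Disease",
                 "x": "Compound", "y": "Compound", "z": "Compound"}
        kg = KnowledgeGraph(
            [("x", "links", "d1"), ("y", "links", "d2"), ("z", "links", "d1")],
            types,
        )
        model = indicator_model(
            ["d1", "d2", "x", "y", "z"], ["treats_inv"],
            {("d1", "x"): 3.0, ("d1", "y"): 2.0, ("d1", "z"): 1.0,
             ("d2", "x"): 1.0, ("d2", "y"): 2.0, ("d2", "z"): 3.0},
        )
        out = case_study_ranks(model, ["d1", "d2"], kg, ["x"])
        assert out["mean_ranks"]["x"] == pytest.approx(
            (out["ranks"]["d1"]["x"] + out["ranks"]["d2"]["x"]) / 2
        )
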