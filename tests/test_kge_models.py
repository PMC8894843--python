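"""Scoring functions, negative sampling and the training loop."""

import numpy as np
import pytest
from scipy.stats import chisquare

from kgfilter.kg_core import KGError, KnowledgeGraph
from kgfilter.kge_models import (
    EmbeddingModel,
    TrainConfig,
    load_model,
    sample_negatives,
    save_model,
    score,
    train,
)
from kgfilter.preprocess import add_inverses_to_bundle, make_holdout_splits
from kgfilter.synthetic_data import SynthConfig, generate

from oracles import brute_model_score


def make_model(scorer, entities, relations, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    width = dim * (2 if scorer == "complex" else 1)
    return EmbeddingModel(
        scorer=scorer,
        dimension=dim,
        entity_index={e: i for i, e in enumerate(entities)},
        relation_index={r: i for i, r in enumerate(relations)},
        entity_emb=rng.normal(size=(len(entities), width)),
        relation_emb=rng.normal(size=(len(relations), width)),
    )


class TestScoring:
    def test_translational_exact_translation_scores_zero(self):
        m = make_model("transe", ["a", "b"], ["r"])
        m.entity_emb[1] = m.entity_emb[0] + m.relation_emb[0]
        assert score(m, ("a", "r", "b")) == pytest.approx(0.0)

    def test_bilinear_diagonal_all_ones(self):
        m = make_model("distmult", ["a", "b"], ["r"], dim=4)
        m.entity_emb[:] = 1.0
        m.relation_emb[:] = 1.0
        assert score(m, ("a", "r", "b")) == pytest.approx(4.0)

    def test_complex_reduces_to_distmult_with_zero_imaginary(self):
        rng = np.random.default_rng(3)
        real = rng.normal(size=(3, 4))
        rel = rng.normal(size=(1, 4))
        dm = make_model("distmult", ["a", "b", "c"], ["r"], dim=4)
        dm.entity_emb, dm.relation_emb = real, rel
        cx = make_model("complex", ["a", "b", "c"], ["r"], dim=4)
        cx.entity_emb = np.concatenate([real, np.zeros_like(real)], axis=1)
        cx.relation_emb = np.concatenate([rel, np.zeros_like(rel)], axis=1)
        for t in (("a", "r", "b"), ("c", "r", "a")):
            assert score(cx, t) == pytest.approx(score(dm, t))

    def test_translational_shift_invariance(self):
        m = make_model("transe", ["a", "b"], ["r"])
        before = score(m, ("a", "r", "b"))
        m.entity_emb += 17.3  # common shift of all entity embeddings
        assert score(m, ("a", "r", "b")) == pytest.approx(before)

    @pytest.mark.parametrize("scorer", ["transe", "distmult", "complex"])
    def test_matches_brute_force_formula(self, scorer):
        m = make_model(scorer, [f"e{i}" for i in range(5)], ["r0", "r1"], seed=9)
        triples = [(f"e{i}", f"r{i % 2}", f"e{(i + 2) % 5}") for i in range(5)]
        for t in triples:
            assert score(m, t) == pytest.approx(brute_model_score(m, t), rel=1e-10)

    @pytest.mark.parametrize("scorer", ["transe", "distmult", "complex"])
    def test_ranking_agrees_with_brute_force(self, scorer):
        m = make_model(scorer, [f"e{i}" for i in range(5)], ["r"], seed=4)
        cands = [(f"e0", "r", f"e{i}") for i in range(1, 5)]
        ours = sorted(cands, key=lambda t: -score(m, t))
        brute = sorted(cands, key=lambda t: -brute_model_score(m, t))
        assert ours == brute

    def test_unknown_entity_raises(self):
        m = make_model("distmult", ["a"], ["r"])
        with pytest.raises(KGError):
            score(m, ("a", "r", "ghost"))


class TestNegativeSampling:
    def test_forced_head_corruption_on_two_entity_kg(self):
        kg = KnowledgeGraph([("a", "r", "b")], {"a": "X", "b": "Y"})
        negs = sample_negatives([("a", "r", "b")], kg, k=20,
                                rng=np.random.default_rng(0))
        assert len(negs) == 20
        # only corruptions not observed: (b,r,b), (a,r,a), (b,r,a)
        assert ("a", "r", "b") not in negs

    def test_relation_always_preserved(self):
        kg = KnowledgeGraph(
            [(f"e{i}", "r", f"e{i+1}") for i in range(5)],
            {f"e{i}": "X" for i in range(6)},
        )
        negs = sample_negatives(sorted(kg.triples), kg, k=7,
                                rng=np.random.default_rng(1))
        assert all(r == "r" for _, r, _ in negs)

    def test_replacement_distribution_matches_enumeration(self):
        """chi-square of replacement entities against the exact distribution
        implied by head/tail coin + uniform draw + observed-triple rejection."""
        ents = [f"e{i}" for i in range(10)]
        ring = [(ents[i], "link", ents[(i + 1) % 10]) for i in range(10)]
        kg = KnowledgeGraph(ring + [("e0", "r", "e1")], {e: "X" for e in ents})
        pos = ("e0", "r", "e1")
        negs = sample_negatives([pos] * 10_000, kg, k=1,
                                rng=np.random.default_rng(5))
        counts = {e: 0 for e in ents}
        for h, _, t in negs:
            counts[h if h != "e0" else t] += 1
        # head side excludes e0 (would recreate the observed triple),
        # tail side excludes e1: each remaining entity 1/9 per side
        expected = []
        for e in ents:
            p = (0.5 / 9) * ((e != "e0") + (e != "e1"))
            expected.append(p * 10_000)
        stat = chisquare(list(counts.values()), expected)
        assert stat.pvalue > 1e-3


def tiny_bundle(seed=0, **synth_overrides):
    synth = dict(n_compound=12, n_disease=8, n_gene=24, n_anatomy=4,
                 n_sideeffect=8, n_noise=10, n_noise_internal_edges=15,
                 n_noise_attachments=12, n_gene_gene_edges=16, seed=seed)
    synth.update(synth_overrides)
    kg = generate(SynthConfig(**synth))
    bundle = make_holdout_splits(kg, "treats", 0.2, 0.2, seed=seed + 1)
    return kg, add_inverses_to_bundle(bundle)


class TestTraining:
    def test_deterministic_given_seed(self):
        _, bundle = tiny_bundle(seed=2)
        cfg = TrainConfig(dimension=8, epochs_max=6, seed=11, min_epochs=6)
        _, c1 = train("distmult", bundle, cfg)
        _, c2 = train("distmult", bundle, cfg)
        assert c1.val_mrr == c2.val_mrr
        assert c1.train_loss == c2.train_loss

    def test_curve_bookkeeping_on_early_stop(self):
        _, bundle = tiny_bundle(seed=3)
        cfg = TrainConfig(dimension=8, epochs_max=200, patience=2,
                          min_epochs=1, seed=7)
        _, curves = train("distmult", bundle, cfg)
        assert len(curves.train_loss) == len(curves.val_mrr)
        if len(curves.train_loss) < cfg.epochs_max:  # early stopped
            assert len(curves.train_loss) == curves.best_epoch + cfg.patience + 1
        assert curves.val_mrr[curves.best_epoch] == max(curves.val_mrr)

    def test_best_epoch_snapshot_returned(self):
        from kgfilter.evaluation import evaluate_task

        kg, bundle = tiny_bundle(seed=4)
        cfg = TrainConfig(dimension=8, epochs_max=15, seed=5, min_epochs=15)
        model, curves = train("distmult", bundle, cfg)
        redo = evaluate_task(model, None, bundle, "validation")
        assert redo["mrr"] == pytest.approx(curves.val_mrr[curves.best_epoch])

    @pytest.mark.parametrize("scorer", ["distmult", "transe"])
    def test_planted_signal_beats_random_baseline(self, scorer):
        """On a strongly planted toy graph the learned model should rank
        held-out treats pairs better than chance, across 3 seeds."""
        from kgfilter.evaluation import evaluate_task, random_baseline
        from kgfilter.kge_models import score_batch

        better = 0
        for seed in (0, 1, 2):
            kg, bundle = tiny_bundle(seed=seed)
            cfg = TrainConfig(dimension=16, epochs_max=40, seed=seed, min_epochs=10)
            model, _ = train(scorer, bundle, cfg)
            summary = evaluate_task(model, kg, bundle, "validation")
            heads = kg.entities_of_type("Compound")
            tails = kg.entities_of_type("Disease")
            eidx, ridx = model.entity_index, model.relation_index
            table = {}
            for h in heads:
                t_ids = np.array([eidx[t] for t in tails])
                s = score_batch(model, np.full(t_ids.size, eidx[h]),
                                np.full(t_ids.size, ridx["treats"]), t_ids)
                table.update({(h, t): float(v) for t, v in zip(tails, s)})
            truth = {(h, t) for h, r, t in bundle.validation if r == "treats"}
            base = random_baseline(table, truth, n_rep=50,
                                   rng=np.random.default_rng(seed))
            better += summary["mrr"] > base
        assert better >= 2

    def test_empty_train_split_raises(self):
        _, bundle = tiny_bundle(seed=5)
        bundle.train = set()
        with pytest.raises(KGError):
            train("distmult", bundle, TrainConfig(epochs_max=1))


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path):
        m = make_model("complex", ["a", "b", "c"], ["r", "s"], dim=3, seed=2)
        save_model(m, tmp_path)
        back = load_model(tmp_path)
        assert back.scorer == "complex" and back.dimension == 3
        for t in (("a", "r", "b"), ("c", "s", "a")):
            assert score(back, t) == pytest.approx(score(m, t), rel=1e-6)
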