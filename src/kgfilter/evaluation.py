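"""Type-constrained filtered ranking, MRR, baselines and diagnostics.

Link prediction for drug repurposing is evaluated only on the target
relation (treats and its inverse).  For a query ``(h, r, t)`` the
candidate tails are all entities of the true tail's type, excluding the
true tail itself and every tail t' with ``(h, r, t')`` observed anywhere
in the data ("filtered" ranking), optionally intersected with an
evaluable-entity set shared between an original and a filtered graph.
The metric is the filtered Mean Reciprocal Rank

    MRR = (1/|Q|) * sum_i 1 / rank_i

where ``rank_i`` is the rank of the true tail among its candidates.
Ties are handled realistically: equal-scoring candidates contribute half
their count (rounded up) to the rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _kl_divergence

from .kg_core import EntityType, KGError, KnowledgeGraph, Triple
from .kge_models import EmbeddingModel, score_batch
from .preprocess import SplitBundle

logger = logging.getLogger(__name__)

N_DIAGNOSTIC_BINS = 50


@dataclass(frozen=True)
class RankResult:
    """Rank of one query's true tail among its candidates."""

    query: Triple
    rank: int
    n_candidates: int


@dataclass
class DistributionDiagnostic:
    """Scaled positive/negative score samples and their divergence."""

    positive_scores: np.ndarray
    negative_scores: np.ndarray
    divergence: float


# -- candidate construction -------------------------------------------


def candidates(
    kg: KnowledgeGraph | None,
    query: Triple,
    evaluable: set[str] | None = None,
    observed: set[Triple] | None = None,
    entity_types: Mapping[str, EntityType] | None = None,
) -> set[str]:
    """Type-constrained filtered candidate tails for ``query``.

    All entities of the true tail's type, minus the true tail, minus every
    tail already observed with the query's head and relation, intersected
    with ``evaluable`` when given.  ``observed`` defaults to the graph's
    triples; pass a larger set (e.g. all splits with inverses) to filter
    against holdout facts as well.
    """
    h, r, t = query
    if entity_types is None:
        if kg is None:
            raise ValueError("either kg or entity_types is required")
        entity_types = kg.entity_types
    if t not in entity_types:
        raise KGError(f"query tail {t!r} not in the graph")
    if observed is None:
        observed = kg.triples if kg is not None else set()
    tail_type = entity_types[t]
    cands = {
        e
        for e, et in entity_types.items()
        if et == tail_type and e != t and (h, r, e) not in observed
    }
    if evaluable is not None:
        cands &= evaluable
    return cands


def filtered_rank(
    model: EmbeddingModel, query: Triple, cands: set[str]
) -> RankResult:
    """Rank the true tail against its candidates under the model's scores.

    rank = 1 + (# candidates scoring strictly higher)
             + ceil((# candidates scoring exactly equal) / 2).
    """
    h, r, t = query
    eidx, ridx = model.entity_index, model.relation_index
    order = sorted(cands)
    if not order:
        return RankResult(query, 1, 0)
    t_ids = np.array([eidx[c] for c in order] + [eidx[t]])
    h_ids = np.full(t_ids.size, eidx[h])
    r_ids = np.full(t_ids.size, ridx[r])
    s = score_batch(model, h_ids, r_ids, t_ids)
    true_score = s[-1]
    cand_scores = s[:-1]
    n_higher = int(np.sum(cand_scores > true_score))
    n_equal = int(np.sum(cand_scores == true_score))
    rank = 1 + n_higher + (n_equal + 1) // 2
    return RankResult(query, rank, len(cands))


def mrr(ranks: Sequence[RankResult]) -> float:
    """Mean reciprocal rank; 1.0 means every true triple ranks first."""
    if not ranks:
        raise ValueError("cannot average an empty rank list")
    return float(np.mean([1.0 / r.rank for r in ranks]))


def hits_at(ranks: Sequence[RankResult], k: int) -> float:
    return float(np.mean([r.rank <= k for r in ranks]))


def evaluate_task(
    model: EmbeddingModel,
    kg_full: KnowledgeGraph | None,
    bundle: SplitBundle,
    which: str = "validation",
    evaluable: set[str] | None = None,
) -> dict:
    """Rank every holdout target triple (both directions, i.e. treats and
    treats-inverse queries) and summarize MRR and hits@{1,3,10}.

    Observed facts for filtering are the union of all three splits (with
    their inverses) and, when ``kg_full`` is given, its triples plus their
    inverses under the bundle's suffix.
    """
    holdout = bundle.holdout(which)
    if not holdout:
        raise KGError(f"{which} split is empty")
    observed = set(bundle.all_triples)
    if kg_full is not None:
        observed |= kg_full.triples
        observed |= {
            (t, r + bundle.inverse_suffix, h) for h, r, t in kg_full.triples
        }
    entity_types = (
        kg_full.entity_types if kg_full is not None else bundle.entity_types
    )
    target = bundle.target_relation
    inverse_target = target + bundle.inverse_suffix
    queries = sorted(t for t in holdout if t[1] in (target, inverse_target))
    if not queries:
        raise KGError(f"no target-relation queries in the {which} split")
    results = [
        filtered_rank(
            model,
            q,
            candidates(
                None, q, evaluable=evaluable, observed=observed,
                entity_types=entity_types,
            ),
        )
        for q in queries
    ]
    return {
        "mrr": mrr(results),
        "hits@1": hits_at(results, 1),
        "hits@3": hits_at(results, 3),
        "hits@10": hits_at(results, 10),
        "n_queries": len(results),
        "results": results,
    }


# -- random-classifier baseline ---------------------------------------


def _rank_with_ties(scores: np.ndarray, pos: int) -> int:
    s = scores[pos]
    higher = int(np.sum(scores > s))
    equal = int(np.sum(scores == s)) - 1
    return 1 + higher + (equal + 1) // 2


def random_baseline(
    score_table: Mapping[tuple[str, str], float],
    truth: set[tuple[str, str]],
    n_rep: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """MRR of fixed scores against a randomized ground truth.

    Per repetition, the set of true pairs in each query row (same head) is
    replaced by an equally sized uniform draw from the row's columns; the
    filtered MRR of the fixed scores against that randomized truth is
    computed, and the mean over ``n_rep`` repetitions is returned.  The
    result depends only on score ranks, so it is invariant to monotone
    transforms and measures pure task difficulty.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows: dict[str, list[str]] = {}
    for (h, t) in sorted(score_table):
        rows.setdefault(h, []).append(t)
    n_true = {h: sum((h, t) in truth for t in ts) for h, ts in rows.items()}
    reps = []
    for _ in range(n_rep):
        recips = []
        for h, tails in rows.items():
            if n_true[h] == 0:
                continue
            scores = np.array([score_table[(h, t)] for t in tails])
            chosen = rng.choice(len(tails), size=n_true[h], replace=False)
            chosen_set = set(chosen.tolist())
            for pos in chosen_set:
                # filtered: other true tails of this row are excluded
                mask = np.array(
                    [i == pos or i not in chosen_set for i in range(len(tails))]
                )
                sub = scores[mask]
                sub_pos = int(np.sum(mask[:pos]))
                recips.append(1.0 / _rank_with_ties(sub, sub_pos))
        if recips:
            reps.append(float(np.mean(recips)))
    return float(np.mean(reps))


# -- score-distribution diagnostic ------------------------------------


def _scale_batch(s: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "sigmoid":
        return 1.0 / (1.0 + np.exp(-s))
    lo, hi = s.min(), s.max()
    if hi == lo:
        logger.info("degenerate diagnostic batch (all scores equal)")
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def score_distribution_diagnostic(
    model: EmbeddingModel,
    train_triples: KnowledgeGraph | set[Triple],
    n_samples: int = 200_000,
    batch_size: int = 2000,
    rng: np.random.Generator | None = None,
    scaling: str = "minmax",
) -> DistributionDiagnostic:
    """Compare score distributions of positive and corrupted triples.

    Draws ``n_samples`` positives (with replacement) from the training
    triples and as many head/tail corruptions, scores them in batches of
    ``batch_size`` scaled to [0, 1] per batch, and reports the
    Kullback-Leibler divergence between the negative and positive
    histogram densities (50 shared bins, add-one smoothing).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    triples = (
        sorted(train_triples.triples)
        if isinstance(train_triples, KnowledgeGraph)
        else sorted(train_triples)
    )
    if not triples:
        raise KGError("no training triples to sample from")
    eidx, ridx = model.entity_index, model.relation_index
    H = np.array([eidx[h] for h, _, _ in triples])
    R = np.array([ridx[r] for _, r, _ in triples])
    T = np.array([eidx[t] for _, _, t in triples])
    observed = set(zip(H.tolist(), R.tolist(), T.tolist()))
    n_entities = len(eidx)

    pick = rng.integers(len(triples), size=n_samples)
    ph, pr, pt = H[pick], R[pick], T[pick]
    from .kge_models import _sample_negative_indices

    nh, nr, nt = _sample_negative_indices(ph, pr, pt, n_entities, 1, observed, rng)

    def _scored(hs, rs, ts):
        out = []
        for i in range(0, hs.size, batch_size):
            s = score_batch(model, hs[i : i + batch_size], rs[i : i + batch_size],
                            ts[i : i + batch_size])
            out.append(_scale_batch(s, scaling))
        return np.concatenate(out)

    pos = _scored(ph, pr, pt)
    neg = _scored(nh, nr, nt)
    bins = np.linspace(0.0, 1.0, N_DIAGNOSTIC_BINS + 1)
    pos_hist = np.histogram(pos, bins=bins)[0] + 1.0  # add-one smoothing
    neg_hist = np.histogram(neg, bins=bins)[0] + 1.0
    div = float(_kl_divergence(neg_hist, pos_hist))
    return DistributionDiagnostic(pos, neg, div)


# -- case-study ranking ------------------------------------------------


def case_study_ranks(
    model: EmbeddingModel,
    disease_entities: Sequence[str],
    kg: KnowledgeGraph,
    highlight_compounds: Sequence[str],
    relation: str = "treats_inv",
    compound_type: EntityType = "Compound",
) -> dict:
    """Rank all compounds per disease entity under (disease, treats⁻¹, compound).

    Returns each highlighted compound's rank per disease, its mean rank
    across diseases, and the expected median rank floor(N/2) for N
    compounds (a rank below it means higher-than-average priority).
    """
    compounds = kg.entities_of_type(compound_type)
    for c in highlight_compounds:
        if c not in kg:
            raise KGError(f"highlight compound {c!r} not in the graph")
    eidx, ridx = model.entity_index, model.relation_index
    t_ids = np.array([eidx[c] for c in compounds])
    ranks: dict[str, dict[str, int]] = {}
    for d in disease_entities:
        h_ids = np.full(t_ids.size, eidx[d])
        r_ids = np.full(t_ids.size, ridx[relation])
        s = score_batch(model, h_ids, r_ids, t_ids)
        ranks[d] = {
            c: _rank_with_ties(s, compounds.index(c)) for c in highlight_compounds
        }
    mean_ranks = {
        c: float(np.mean([ranks[d][c] for d in disease_entities]))
        for c in highlight_compounds
    }
    return {
        "ranks": ranks,
        "mean_ranks": mean_ranks,
        "n_compounds": len(compounds),
        "expected_median_rank": len(compounds) // 2,
    }


def write_evaluation_report(summary: dict, detail_path, summary_path) -> None:
    """Write per-query ranks and the aggregate metrics as TSVs."""
    with open(detail_path, "w") as fh:
        fh.write("head\trelation\ttail\trank\tn_candidates\n")
        for r in summary["results"]:
            h, rel, t = r.query
            fh.write(f"{h}\t{rel}\t{t}\t{r.rank}\t{r.n_candidates}\n")
    with open(summary_path, "w") as fh:
        for key in ("mrr", "hits@1", "hits@3", "hits@10", "n_queries"):
            fh.write(f"{key}\t{summary[key]}\n")
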