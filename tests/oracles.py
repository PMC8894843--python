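"""Independent brute-force oracles, written from the definitions.

These deliberately re-derive scoring, ranking and MRR with plain Python
loops so they share no code path with the package implementation.
"""

import math


def brute_score(scorer: str, h, r, t) -> float:
    if scorer == "transe":
        return -math.sqrt(sum((hi + ri - ti) ** 2 for hi, ri, ti in zip(h, r, t)))
    if scorer == "distmult":
        return sum(hi * ri * ti for hi, ri, ti in zip(h, r, t))
    if scorer == "complex":
        d = len(h) // 2
        total = 0.0
        for k in range(d):
            hr, hi = h[k], h[d + k]
            rr, ri = r[k], r[d + k]
            tr, ti = t[k], t[d + k]
            total += (hr * rr - hi * ri) * tr + (hr * ri + hi * rr) * ti
        return total
    raise ValueError(scorer)


def brute_model_score(model, triple) -> float:
    h, r, t = triple
    return brute_score(
        model.scorer,
        list(model.entity_emb[model.entity_index[h]]),
        list(model.relation_emb[model.relation_index[r]]),
        list(model.entity_emb[model.entity_index[t]]),
    )


def brute_rank(true_score: float, candidate_scores) -> int:
    higher = sum(1 for s in candidate_scores if s > true_score)
    equal = sum(1 for s in candidate_scores if s == true_score)
    return 1 + higher + math.ceil(equal / 2)


def brute_task_mrr(model, kg_full, bundle, which, evaluable=None) -> float:
    """From-scratch filtered type-constrained MRR over the holdout."""
    observed = set(bundle.train) | set(bundle.validation) | set(bundle.test)
    if kg_full is not None:
        observed |= set(kg_full.triples)
        observed |= {
            (t, r + bundle.inverse_suffix, h) for h, r, t in kg_full.triples
        }
    types = kg_full.entity_types if kg_full is not None else bundle.entity_types
    target = bundle.target_relation
    holdout = bundle.validation if which == "validation" else bundle.test
    queries = [
        q for q in sorted(holdout)
        if q[1] in (target, target + bundle.inverse_suffix)
    ]
    recips = []
    for h, r, t in queries:
        cands = [
            e for e, et in types.items()
            if et == types[t] and e != t and (h, r, e) not in observed
            and (evaluable is None or e in evaluable)
        ]
        true_score = brute_model_score(model, (h, r, t))
        cand_scores = [brute_model_score(model, (h, r, e)) for e in cands]
        recips.append(1.0 / brute_rank(true_score, cand_scores))
    return sum(recips) / len(recips)
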