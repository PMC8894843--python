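"""Preprocessing for treats-prediction: ambiguity removal, relation
unification, contradiction checks, and leakage-safe holdout construction.

The pipeline order is fixed and enforced:

1. remove relations between the task's entity-type pair that are not
   treats-like (ambiguity removal),
2. unify the remaining treats-like relations under one name,
3. sample validation/test holdouts from the target relation,
4. add inverse relations *per split* (so no inverse leaks across splits),
5. after metapath filtering, restrict the holdouts to retained entities so
   the original and filtered graphs are evaluated on identical holdout sets.

Holdouts are taken *before* filtering; restriction happens *after*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .kg_core import EntityType, KGError, KnowledgeGraph, Triple

logger = logging.getLogger(__name__)

DEFAULT_INVERSE_SUFFIX = "_inv"


class ProtocolError(RuntimeError):
    """Raised when preprocessing steps are requested out of order."""


@dataclass
class SplitBundle:
    """Train/validation/test triple sets for one link-prediction task.

    ``entity_types`` snapshots the graph's type mapping at split time so
    that downstream training and evaluation can type-constrain candidates
    without re-reading the graph.
    """

    train: set[Triple]
    validation: set[Triple]
    test: set[Triple]
    target_relation: str
    inverse_suffix: str = DEFAULT_INVERSE_SUFFIX
    entity_types: dict[str, EntityType] = field(default_factory=dict)
    inverses_added: bool = False
    seed: int | None = None
    valid_fraction: float | None = None
    test_fraction: float | None = None

    def holdout(self, which: str) -> set[Triple]:
        if which not in ("validation", "test"):
            raise ValueError("which must be 'validation' or 'test'")
        return self.validation if which == "validation" else self.test

    @property
    def all_triples(self) -> set[Triple]:
        return self.train | self.validation | self.test


def remove_ambiguous_relations(
    kg: KnowledgeGraph,
    head_type: EntityType,
    tail_type: EntityType,
    keep_relations: set[str],
) -> tuple[KnowledgeGraph, int]:
    """Drop triples between ``head_type`` and ``tail_type`` entities (either
    orientation) whose relation is not in ``keep_relations``.

    Returns the cleaned graph and the number of removed triples.  Applying
    the operation twice is a no-op.
    """
    if not keep_relations:
        raise ValueError("keep_relations must be non-empty")
    vocab = kg.type_vocabulary
    for t in (head_type, tail_type):
        if t not in vocab:
            raise KGError(f"unknown entity type {t!r}")
    pair = {head_type, tail_type}
    kept = []
    removed = 0
    for h, r, t in kg.triples:
        if {kg.type_of(h), kg.type_of(t)} == pair and r not in keep_relations:
            removed += 1
        else:
            kept.append((h, r, t))
    return KnowledgeGraph(kept, kg.entity_types), removed


def unify_relations(
    kg: KnowledgeGraph,
    source_relations: set[str],
    unified_name: str,
) -> tuple[KnowledgeGraph, int]:
    """Rename every triple with a relation in ``source_relations`` to
    ``unified_name``; overlapping pairs collapse, and the number of triples
    lost to the collapse is returned.
    """
    unknown = set(source_relations) - set(kg.relations)
    if unknown:
        raise KGError(f"source relations not in graph: {sorted(unknown)}")
    if unified_name in kg.relations and unified_name not in source_relations:
        warnings.warn(
            f"unified name {unified_name!r} already used by an existing relation",
            stacklevel=2,
        )
    renamed = [
        (h, unified_name if r in source_relations else r, t)
        for h, r, t in kg.triples
    ]
    new_kg = KnowledgeGraph(renamed, kg.entity_types)
    return new_kg, len(kg.triples) - len(new_kg.triples)


def count_contradictions(
    kg: KnowledgeGraph, opposed_pairs: set[tuple[str, str]]
) -> int:
    """Count entity pairs (e1, e2) linked by both relations of an opposed
    pair, e.g. upregulates and downregulates simultaneously."""
    n = 0
    by_rel: dict[str, set[tuple[str, str]]] = {}
    for h, r, t in kg.triples:
        by_rel.setdefault(r, set()).add((h, t))
    for r_up, r_down in opposed_pairs:
        n += len(by_rel.get(r_up, set()) & by_rel.get(r_down, set()))
    return n


def make_holdout_splits(
    kg: KnowledgeGraph,
    target_relation: str,
    valid_fraction: float,
    test_fraction: float,
    seed: int,
    inverse_suffix: str = DEFAULT_INVERSE_SUFFIX,
) -> SplitBundle:
    """Partition the target-relation triples into train/validation/test by
    uniform sampling without replacement (floor rounding; the remainder and
    all non-target triples stay in train).

    Must run before inverse relations are introduced, otherwise inverse
    twins of one fact could land in different splits and leak.
    """
    if any(r.endswith(inverse_suffix) for r in kg.relations):
        raise ProtocolError(
            "splits must be taken before inverse relations are introduced"
        )
    if valid_fraction < 0 or test_fraction < 0 or valid_fraction + test_fraction >= 1:
        raise ValueError("fractions must be >= 0 and sum to < 1")
    targets = sorted(t for t in kg.triples if t[1] == target_relation)
    if not targets:
        raise KGError(f"graph has no {target_relation!r} triples")
    n_valid = int(len(targets) * valid_fraction)
    n_test = int(len(targets) * test_fraction)
    if (valid_fraction > 0 and n_valid == 0) or (test_fraction > 0 and n_test == 0):
        warnings.warn("holdout fraction yields zero triples", stacklevel=2)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(targets))
    valid = {targets[i] for i in perm[:n_valid]}
    test = {targets[i] for i in perm[n_valid : n_valid + n_test]}
    train = set(kg.triples) - valid - test
    return SplitBundle(
        train=train,
        validation=valid,
        test=test,
        target_relation=target_relation,
        inverse_suffix=inverse_suffix,
        entity_types=kg.entity_types,
        seed=seed,
        valid_fraction=valid_fraction,
        test_fraction=test_fraction,
    )


def add_inverse_relations(split: set[Triple], inverse_suffix: str = DEFAULT_INVERSE_SUFFIX) -> set[Triple]:
    """Return the split plus one inverse triple (t, r+suffix, h) per triple.

    Applied to each split separately so no inverse crosses split borders.
    """
    if any(r.endswith(inverse_suffix) for _, r, _ in split):
        raise ProtocolError(
            f"a relation already carries the inverse suffix {inverse_suffix!r}"
        )
    out = set(split)
    out.update((t, r + inverse_suffix, h) for h, r, t in split)
    return out


def add_inverses_to_bundle(bundle: SplitBundle) -> SplitBundle:
    """Introduce inverse relations in all three splits, each separately."""
    if bundle.inverses_added:
        raise ProtocolError("inverse relations were already introduced")
    return replace(
        bundle,
        train=add_inverse_relations(bundle.train, bundle.inverse_suffix),
        validation=add_inverse_relations(bundle.validation, bundle.inverse_suffix),
        test=add_inverse_relations(bundle.test, bundle.inverse_suffix),
        inverses_added=True,
    )


def restrict_holdouts(bundle: SplitBundle, retained_entities: set[str]) -> SplitBundle:
    """Drop every holdout triple with an endpoint outside ``retained_entities``.

    Used after metapath filtering: evaluating the original and the filtered
    graph on the restricted holdouts makes the two evaluations set-equal.
    The train split is left untouched.
    """

    def _keep(s: set[Triple]) -> set[Triple]:
        return {t for t in s if t[0] in retained_entities and t[2] in retained_entities}

    return replace(bundle, validation=_keep(bundle.validation), test=_keep(bundle.test))


# -- persistence -------------------------------------------------------


def write_splits(bundle: SplitBundle, out_dir) -> None:
    """Write train/validation/test TSVs plus a YAML manifest."""
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("train", "validation", "test"):
        with open(out / f"{name}.tsv", "w") as fh:
            for h, r, t in sorted(getattr(bundle, name)):
                fh.write(f"{h}\t{r}\t{t}\n")
    manifest = {
        "target_relation": bundle.target_relation,
        "inverse_suffix": bundle.inverse_suffix,
        "inverses_added": bundle.inverses_added,
        "seed": bundle.seed,
        "valid_fraction": bundle.valid_fraction,
        "test_fraction": bundle.test_fraction,
        "counts": {
            "train": len(bundle.train),
            "validation": len(bundle.validation),
            "test": len(bundle.test),
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
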