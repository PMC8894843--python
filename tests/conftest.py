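"""Shared fixtures: small hand-enumerable graphs."""

import numpy as np
import pytest

from kgfilter.kg_core import KnowledgeGraph


@pytest.fixture
def star_kg():
    """Star: center c0 linked to 3 genes and 2 diseases."""
    types = {"c0": "Compound", "g1": "Gene", "g2": "Gene", "g3": "Gene",
             "d1": "Disease", "d2": "Disease"}
    triples = [
        ("c0", "binds", "g1"), ("c0", "binds", "g2"), ("g3", "binds", "c0"),
        ("c0", "treats", "d1"), ("d2", "treated_by", "c0"),
    ]
    return KnowledgeGraph(triples, types)


@pytest.fixture
def path_kg():
    """Minimal Compound-Gene-Disease path: c - g - d."""
    return KnowledgeGraph(
        [("c", "binds", "g"), ("g", "associates", "d")],
        {"c": "Compound", "g": "Gene", "d": "Disease"},
    )


@pytest.fixture
def fork_kg():
    """Compound adjacent to two genes: a forced 50/50 branch."""
    return KnowledgeGraph(
        [("c", "binds", "g1"), ("c", "binds", "g2")],
        {"c": "Compound", "g1": "Gene", "g2": "Gene"},
    )


def random_typed_kg(rng: np.random.Generator, n_entities: int = 30,
                    n_triples: int = 60, types=("Compound", "Gene", "Disease")):
    """A random typed multigraph for property tests."""
    names = [f"e{i}" for i in range(n_entities)]
    entity_types = {e: types[rng.integers(len(types))] for e in names}
    triples = []
    for _ in range(n_triples):
        h, t = rng.choice(n_entities, size=2, replace=False)
        triples.append((names[h], f"r{rng.integers(3)}", names[t]))
    return KnowledgeGraph(triples, entity_types)
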