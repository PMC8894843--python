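"""Typed multi-relational knowledge graphs: data model, TSV I/O, statistics.

A knowledge graph here is a set of (head, relation, tail) triples over
entities that each carry exactly one type (e.g. ``Compound``, ``Disease``,
``Gene``).  Neighborhood queries are direction-agnostic: ``(a, r, b)`` makes
``a`` and ``b`` adjacent regardless of which end a query starts from, which
is what lets metapath walkers traverse edges both ways.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: An entity type is a short string label such as "Compound" or "Gene".
EntityType = str

#: A triple is an immutable (head, relation, tail) tuple of strings.
Triple = tuple[str, str, str]

#: Sentinel for entity ids that encode their own type as "Type::id".
TYPE_PREFIX_RULE = "prefix"
_PREFIX_SEP = "::"


class KGError(ValueError):
    """Raised for malformed graphs, unknown entities or unresolvable types."""


@dataclass(frozen=True)
class GraphStats:
    """Descriptive statistics of a knowledge graph.

    ``avg_degree`` uses the direction-agnostic convention
    ``2 * n_triples / n_entities`` (each triple contributes one degree to
    each endpoint).  ``avg_out_degree`` is the per-direction variant
    ``n_triples / n_entities`` for comparison with sources that count each
    triple once.
    """

    n_entities: int
    n_triples: int
    n_relations: int
    avg_degree: float
    avg_out_degree: float
    type_frequency: dict[EntityType, float]


class KnowledgeGraph:
    """A typed multi-relational graph stored as a set of triples.

    Parameters
    ----------
    triples:
        Iterable of ``(head, relation, tail)``. Duplicates collapse with a
        logged count (set semantics).
    entity_types:
        Mapping from entity id to its single type. May cover more entities
        than appear in the triples; entities incident to zero triples are
        dropped with a logged count.
    """

    def __init__(
        self,
        triples: Iterable[Triple],
        entity_types: Mapping[str, EntityType],
    ) -> None:
        raw = list(tuple(t) for t in triples)
        triple_set = set(raw)
        n_dupes = len(raw) - len(triple_set)
        if n_dupes:
            logger.info("collapsed %d duplicate triples", n_dupes)

        used: set[str] = set()
        for h, _, t in triple_set:
            used.add(h)
            used.add(t)
        missing = used - set(entity_types)
        if missing:
            raise KGError(
                f"no type for entity {sorted(missing)[0]!r} "
                f"({len(missing)} untyped entities in total)"
            )
        n_dropped = len(set(entity_types) - used)
        if n_dropped:
            logger.info("dropped %d entities with zero incident triples", n_dropped)

        self._triples: frozenset[Triple] = frozenset(triple_set)
        self._types: dict[str, EntityType] = {e: entity_types[e] for e in used}
        self._relations: frozenset[str] = frozenset(r for _, r, _ in triple_set)
        self._adjacency: dict[str, dict[EntityType, tuple[str, ...]]] | None = None
        self.n_duplicates_collapsed = n_dupes
        self.n_isolated_dropped = n_dropped

    # -- basic views ----------------------------------------------------

    @property
    def triples(self) -> frozenset[Triple]:
        return self._triples

    @property
    def entities(self) -> set[str]:
        return set(self._types)

    @property
    def entity_types(self) -> dict[str, EntityType]:
        return dict(self._types)

    @property
    def relations(self) -> frozenset[str]:
        return self._relations

    @property
    def type_vocabulary(self) -> set[EntityType]:
        return set(self._types.values())

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, entity: str) -> bool:
        return entity in self._types

    def type_of(self, entity: str) -> EntityType:
        try:
            return self._types[entity]
        except KeyError:
            raise KGError(f"unknown entity {entity!r}") from None

    def entities_of_type(self, t: EntityType) -> list[str]:
        """All entity ids of type ``t``, sorted for determinism."""
        return sorted(e for e, et in self._types.items() if et == t)

    # -- adjacency ------------------------------------------------------

    def _build_adjacency(self) -> dict[str, dict[EntityType, tuple[str, ...]]]:
        nbrs: dict[str, set[str]] = {e: set() for e in self._types}
        for h, _, t in self._triples:
            nbrs[h].add(t)
            nbrs[t].add(h)
        adj: dict[str, dict[EntityType, tuple[str, ...]]] = {}
        for e, ns in nbrs.items():
            by_type: dict[EntityType, list[str]] = {}
            for n in ns:
                by_type.setdefault(self._types[n], []).append(n)
            # sorted neighbor tuples make seeded walks reproducible
            adj[e] = {t: tuple(sorted(v)) for t, v in by_type.items()}
        return adj

    @property
    def adjacency(self) -> dict[str, dict[EntityType, tuple[str, ...]]]:
        if self._adjacency is None:
            self._adjacency = self._build_adjacency()
        return self._adjacency

    def typed_neighbors(self, e: str, t: EntityType) -> tuple[str, ...]:
        """Entities of type ``t`` adjacent to ``e`` in either triple direction."""
        if e not in self._types:
            raise KGError(f"unknown entity {e!r}")
        return self.adjacency[e].get(t, ())

    def neighbors(self, e: str) -> set[str]:
        """The untyped neighborhood N(e)."""
        if e not in self._types:
            raise KGError(f"unknown entity {e!r}")
        out: set[str] = set()
        for ns in self.adjacency[e].values():
            out.update(ns)
        return out

    # -- derived graphs -------------------------------------------------

    def induce_subgraph(self, keep: set[str]) -> "KnowledgeGraph":
        """Restrict to ``keep``: retain exactly the triples with both endpoints
        in ``keep``.  Entities left without any incident triple are dropped,
        so the result may have fewer entities than ``keep``.
        """
        unknown = set(keep) - set(self._types)
        if unknown:
            raise KGError(f"unknown entity ids in keep set: {sorted(unknown)[:5]}")
        kept = [t for t in self._triples if t[0] in keep and t[2] in keep]
        return KnowledgeGraph(kept, {e: self._types[e] for e in keep})


def compute_stats(kg: KnowledgeGraph) -> GraphStats:
    """Entity/triple counts, average degree and relative type frequencies."""
    n_ent = len(kg.entities)
    if n_ent == 0:
        raise KGError("cannot compute statistics of an empty graph")
    n_tri = len(kg.triples)
    counts: dict[EntityType, int] = {}
    for t in kg.entity_types.values():
        counts[t] = counts.get(t, 0) + 1
    return GraphStats(
        n_entities=n_ent,
        n_triples=n_tri,
        n_relations=len(kg.relations),
        avg_degree=2.0 * n_tri / n_ent,
        avg_out_degree=n_tri / n_ent,
        type_frequency={t: c / n_ent for t, c in sorted(counts.items())},
    )


# -- I/O ---------------------------------------------------------------


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields]
    return lowered[:3] in (
        ["head", "relation", "tail"],
        ["source", "metaedge", "target"],
        ["h", "r", "t"],
        ["subject", "predicate", "object"],
    ) or lowered[:2] in (["id", "type"], ["id", "kind"], ["id", "label"])


def read_triples_tsv(path: str | Path) -> list[Triple]:
    """Read a head/relation/tail TSV; a header row is auto-detected."""
    triples: list[Triple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise KGError(f"{path}:{lineno}: expected 3 tab-separated columns")
            if lineno == 1 and _looks_like_header(fields):
                continue
            triples.append((fields[0], fields[1], fields[2]))
    return triples


def read_nodes_tsv(path: str | Path) -> dict[str, EntityType]:
    """Read an id/type TSV; a header row is auto-detected."""
    types: dict[str, EntityType] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise KGError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and _looks_like_header(fields):
                continue
            types[fields[0]] = fields[1]
    return types


def _types_from_prefix(triples: Iterable[Triple]) -> dict[str, EntityType]:
    types: dict[str, EntityType] = {}
    for h, _, t in triples:
        for e in (h, t):
            if _PREFIX_SEP not in e:
                raise KGError(
                    f"entity {e!r} does not follow the 'Type::id' encoding"
                )
            types[e] = e.split(_PREFIX_SEP, 1)[0]
    return types


def load_kg(
    triples_path: str | Path,
    type_source: str | Path = TYPE_PREFIX_RULE,
) -> KnowledgeGraph:
    """Load a knowledge graph from a triples TSV.

    ``type_source`` is either the path of a nodes TSV (id, type columns) or
    the string ``"prefix"`` to decode types from ``Type::id`` entity
    identifiers (DRKG dialect).
    """
    triples = read_triples_tsv(triples_path)
    if str(type_source) == TYPE_PREFIX_RULE:
        types = _types_from_prefix(triples)
    else:
        types = read_nodes_tsv(type_source)
    return KnowledgeGraph(triples, types)


def write_kg(kg: KnowledgeGraph, triples_path: str | Path, nodes_path: str | Path | None = None) -> None:
    """Write the graph as triples TSV (and optionally a nodes TSV)."""
    with open(triples_path, "w") as fh:
        for h, r, t in sorted(kg.triples):
            fh.write(f"{h}\t{r}\t{t}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            for e, t in sorted(kg.entity_types.items()):
                fh.write(f"{e}\t{t}\n")


def write_stats(stats: GraphStats, metrics_path: str | Path, freq_path: str | Path) -> None:
    """Write a (metric, value) TSV and a type-frequency TSV."""
    with open(metrics_path, "w") as fh:
        fh.write(f"n_entities\t{stats.n_entities}\n")
        fh.write(f"n_triples\t{stats.n_triples}\n")
        fh.write(f"n_relations\t{stats.n_relations}\n")
        fh.write(f"avg_degree\t{stats.avg_degree:.6g}\n")
        fh.write(f"avg_out_degree\t{stats.avg_out_degree:.6g}\n")
    with open(freq_path, "w") as fh:
        for t, f in stats.type_frequency.items():
            fh.write(f"{t}\t{f:.6g}\n")
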