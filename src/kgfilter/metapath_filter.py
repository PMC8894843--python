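"""Task-driven metapath filtering: the core random-walk subgraph extractor.

A metapath is an ordered sequence of entity types, e.g.
``Compound -> Gene -> Disease``.  A walker starts at every entity of the
first type and repeatedly steps to a uniformly chosen neighbor of the next
required type; walks that reach the final type are *complete*, walks that
dead-end are *stopped*.  The metapath is also traversed in the opposite
direction, starting from entities of the last type.  Complete walks are
then chained end-to-start at shared junction entities ("dominoes") until a
target entity-length is reached; entities appearing in at least one such
concatenated walk form the retained set E', and the filtered graph is the
subgraph of the original induced by E'.

Because every retained entity lies on some complete metapath instance,
everything in the filtered graph sits within half the longest metapath
length of an endpoint-type entity (a Compound or Disease for the shipped
defaults).  Walkers pass through high-degree entities more often, so well
established hub entities are preferentially retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_core import EntityType, KGError, KnowledgeGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metapath:
    """An ordered sequence of at least two entity types."""

    types: tuple[EntityType, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a metapath needs at least two entity types")

    def __len__(self) -> int:
        return len(self.types)

    def reversed(self) -> "Metapath":
        return Metapath(tuple(reversed(self.types)))

    def __str__(self) -> str:
        return ",".join(self.types)

    @classmethod
    def parse(cls, text: str) -> "Metapath":
        return cls(tuple(s.strip() for s in text.split(",") if s.strip()))


@dataclass(frozen=True)
class Walk:
    """A (possibly prematurely stopped) metapath walk.

    ``entities[i]`` has the i-th type of the walk's metapath; consecutive
    entities are adjacent in the source graph.
    """

    entities: tuple[str, ...]
    status: str  # "complete" | "stopped"


@dataclass
class FilterParams:
    """Walker parameters.

    Defaults match the published protocol: 1000 starts per source entity
    and metapath, concatenated walks of 100 entities, 5000 concatenated
    walks per metapath.  ``max_concat_attempts`` caps chain-building
    retries when the walk pool cannot reach the target length.
    """

    starts_per_source: int = 1000
    concat_target_length: int = 100
    n_concat_per_metapath: int = 5000
    seed: int = 0
    max_concat_attempts: int | None = None  # default: 10 x n_concat_per_metapath

    def __post_init__(self) -> None:
        if self.max_concat_attempts is None:
            self.max_concat_attempts = 10 * self.n_concat_per_metapath
        for name in ("starts_per_source", "concat_target_length",
                     "n_concat_per_metapath", "max_concat_attempts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FilterReport:
    """Bookkeeping of one filtering run."""

    n_entities_before: int
    n_entities_after: int
    n_triples_before: int
    n_triples_after: int
    type_retention: dict[EntityType, tuple[int, int]]  # type -> (before, after)
    walk_counts: list[dict] = field(default_factory=list)

    @property
    def entity_reduction(self) -> float:
        return 1.0 - self.n_entities_after / self.n_entities_before

    @property
    def triple_reduction(self) -> float:
        return 1.0 - self.n_triples_after / self.n_triples_before


def single_walk(
    kg: KnowledgeGraph, m: Metapath, start: str, rng: np.random.Generator
) -> Walk:
    """Walk one metapath instance from ``start``.

    At each step the next entity is drawn uniformly from the neighbors of
    the required next type; the walk is complete when the final type is
    reached and stopped as soon as no neighbor of the required type exists.
    """
    if kg.type_of(start) != m.types[0]:
        raise KGError(
            f"start entity {start!r} has type {kg.type_of(start)!r}, "
            f"metapath expects {m.types[0]!r}"
        )
    path = [start]
    for next_type in m.types[1:]:
        nbrs = kg.typed_neighbors(path[-1], next_type)
        if not nbrs:
            return Walk(tuple(path), "stopped")
        path.append(nbrs[rng.integers(len(nbrs))])
    return Walk(tuple(path), "complete")


def run_walker(
    kg: KnowledgeGraph,
    m: Metapath,
    params: FilterParams,
    rng: np.random.Generator | None = None,
) -> tuple[set[Walk], set[Walk]]:
    """Launch ``starts_per_source`` walks from every entity of the first
    type along ``m`` and from every entity of the last type along the
    reversed metapath.  Returns the complete and stopped walk sets, with
    walks stored in the direction they were walked.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    forward_sources = kg.entities_of_type(m.types[0])
    reverse_sources = kg.entities_of_type(m.types[-1])
    if not forward_sources and not reverse_sources:
        raise KGError(
            f"no entities of type {m.types[0]!r} or {m.types[-1]!r} to start from"
        )
    complete: set[Walk] = set()
    stopped: set[Walk] = set()
    for direction, sources in ((m, forward_sources), (m.reversed(), reverse_sources)):
        for src in sources:
            for _ in range(params.starts_per_source):
                w = single_walk(kg, direction, src, rng)
                (complete if w.status == "complete" else stopped).add(w)
    return complete, stopped


def concatenate_walks(
    w_complete: set[Walk],
    params: FilterParams,
    rng: np.random.Generator | None = None,
) -> list[Walk]:
    """Chain complete walks end-to-start at shared junction entities.

    A chain starts from a uniformly drawn complete walk and is extended by
    uniformly drawn walks (with replacement) whose first entity equals the
    chain's current last entity; the junction entity is kept once per join.
    A chain is emitted at the first length >= ``concat_target_length``
    entities; a chain that dead-ends earlier is discarded and a fresh
    attempt started.  Returns ``n_concat_per_metapath`` chains, or fewer
    with a warning once ``max_concat_attempts`` starts are exhausted.
    """
    if not w_complete:
        raise ValueError("cannot concatenate an empty set of complete walks")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pool = sorted(w_complete, key=lambda w: w.entities)
    by_first: dict[str, list[int]] = {}
    for i, w in enumerate(pool):
        by_first.setdefault(w.entities[0], []).append(i)

    chains: list[Walk] = []
    attempts = 0
    while len(chains) < params.n_concat_per_metapath and attempts < params.max_concat_attempts:
        attempts += 1
        chain = list(pool[rng.integers(len(pool))].entities)
        while len(chain) < params.concat_target_length:
            ext = by_first.get(chain[-1])
            if not ext:
                chain = None
                break
            nxt = pool[ext[rng.integers(len(ext))]]
            chain.extend(nxt.entities[1:])
        if chain is not None:
            chains.append(Walk(tuple(chain), "complete"))
    if len(chains) < params.n_concat_per_metapath:
        warnings.warn(
            f"built only {len(chains)}/{params.n_concat_per_metapath} "
            f"concatenated walks after {attempts} attempts",
            stacklevel=2,
        )
    return chains


def collect_entities(w_concatenated: list[Walk]) -> set[str]:
    """Union of all entities appearing in the concatenated walks."""
    out: set[str] = set()
    for w in w_concatenated:
        out.update(w.entities)
    return out


def filter_kg(
    kg: KnowledgeGraph,
    metapaths: list[Metapath],
    params: FilterParams,
) -> tuple[KnowledgeGraph, FilterReport]:
    """Run the full filtering procedure and induce the task-specific graph.

    Per metapath: walk both directions, concatenate the complete walks,
    collect the visited entities; E' is the union over metapaths and the
    result is the subgraph induced by E'.  One independent random stream
    per metapath is derived from ``params.seed`` so per-metapath results
    are individually reproducible.
    """
    if not metapaths:
        raise ValueError("at least one metapath is required")
    retained: set[str] = set()
    walk_counts: list[dict] = []
    seeds = np.random.SeedSequence(params.seed).spawn(len(metapaths))
    for m, ss in zip(metapaths, seeds):
        rng = np.random.default_rng(ss)
        complete, stopped = run_walker(kg, m, params, rng)
        record = {
            "metapath": str(m),
            "n_complete": len(complete),
            "n_stopped": len(stopped),
            "n_concatenated": 0,
        }
        if complete:
            chains = concatenate_walks(complete, params, rng)
            record["n_concatenated"] = len(chains)
            retained |= collect_entities(chains)
        else:
            logger.warning("metapath %s produced no complete walks", m)
        walk_counts.append(record)

    filtered = kg.induce_subgraph(retained)
    before_types: dict[EntityType, int] = {}
    for t in kg.entity_types.values():
        before_types[t] = before_types.get(t, 0) + 1
    after_types: dict[EntityType, int] = {}
    for t in filtered.entity_types.values():
        after_types[t] = after_types.get(t, 0) + 1
    report = FilterReport(
        n_entities_before=len(kg.entities),
        n_entities_after=len(filtered.entities),
        n_triples_before=len(kg.triples),
        n_triples_after=len(filtered.triples),
        type_retention={
            t: (n, after_types.get(t, 0)) for t, n in sorted(before_types.items())
        },
        walk_counts=walk_counts,
    )
    return filtered, report


# -- metapath file I/O -------------------------------------------------


def read_metapaths(path: str | Path) -> list[Metapath]:
    """Read a metapath file: one comma-separated type sequence per line,
    ``#`` comments ignored."""
    out: list[Metapath] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(Metapath.parse(line))
    if not out:
        raise ValueError(f"no metapaths found in {path}")
    return out


def default_metapaths() -> list[Metapath]:
    """Illustrative Compound/Disease metapaths over a Hetionet-like schema.

    These are sensible defaults for experimentation; reproducing published
    full-scale results requires the exact metapath list used there, supplied
    as a user file.
    """
    from importlib.resources import files

    return read_metapaths(files("kgfilter").joinpath("data/default_metapaths.txt"))


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"n_entities_before\t{report.n_entities_before}\n")
        fh.write(f"n_entities_after\t{report.n_entities_after}\n")
        fh.write(f"n_triples_before\t{report.n_triples_before}\n")
        fh.write(f"n_triples_after\t{report.n_triples_after}\n")
        fh.write(f"entity_reduction\t{report.entity_reduction:.6g}\n")
        fh.write(f"triple_reduction\t{report.triple_reduction:.6g}\n")
        for t, (before, after) in report.type_retention.items():
            fh.write(f"type_retention\t{t}\t{before}\t{after}\n")
        for rec in report.walk_counts:
            fh.write(
                "walks\t{metapath}\t{n_complete}\t{n_stopped}\t{n_concatenated}\n".format(**rec)
            )
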