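"""Seeded generator of Hetionet-like heterogeneous knowledge graphs.

The generated graphs have a small biomedical type vocabulary (Compound,
Disease, Gene, Anatomy, SideEffect) plus a ``Noise`` type, and a planted
treats signal: a compound treats a disease with high probability when the
two share at least ``shared_gene_threshold`` gene neighbors, and with low
probability otherwise.  This routes the task signal through
Compound-Gene-Disease neighborhoods, the structure metapath filtering is
designed to exploit.  A "noise appendage" of Noise-type entities hangs off
the core through Noise entities only, so it is unreachable by any metapath
over biomedical types and should be removed by filtering.

Generation is staged over independent seeded streams (core structure,
treats placement, noise) so that analytic expectations about the treats
count can be computed from the core structure alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg_core import KnowledgeGraph, Triple
from .metapath_filter import Metapath

NOISE_TYPE = "Noise"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic graphs.

    Defaults give ~565 entities of which more than half belong to the
    irrelevant Noise portion, mirroring real biomedical graphs where the
    task-relevant core is a small minority.  Noise entities attach to
    Compounds (like registry/article links in real graphs), so the
    irrelevant edges compete with the treats signal for embedding
    capacity.  The whole graph still trains in seconds.
    """

    n_compound: int = 60
    n_disease: int = 40
    n_gene: int = 120
    n_anatomy: int = 15
    n_sideeffect: int = 30
    n_noise: int = 300

    genes_per_compound: int = 3
    genes_per_disease: int = 3
    n_gene_gene_edges: int = 80
    sideeffects_per_compound: int = 2
    anatomies_per_disease: int = 2

    p_high: float = 0.9
    p_low: float = 0.01
    shared_gene_threshold: int = 1

    #: Zipf-like skew of gene attachment: compounds/diseases link to gene i
    #: with weight (i+1)^-exponent, mimicking the hub structure of real
    #: interactomes where well-studied genes carry most connections.
    gene_popularity_exponent: float = 0.5

    n_noise_internal_edges: int = 500
    n_noise_attachments: int = 480
    noise_attachment_type: str = "Compound"

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_high > self.p_low >= 0:
            raise ValueError("need p_high > p_low >= 0")
        for name in ("n_compound", "n_disease", "n_gene", "n_anatomy",
                     "n_sideeffect", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def _core_structure(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Sample every edge except treats: the structure the signal rides on."""
    compounds = _ids("C", config.n_compound)
    diseases = _ids("D", config.n_disease)
    genes = _ids("G", config.n_gene)
    anatomies = _ids("A", config.n_anatomy)
    sideeffects = _ids("SE", config.n_sideeffect)

    weights = np.arange(1, config.n_gene + 1, dtype=float) ** (
        -config.gene_popularity_exponent
    )
    weights /= weights.sum()

    triples: list[Triple] = []
    c_genes: dict[str, set[str]] = {}
    d_genes: dict[str, set[str]] = {}
    for c in compounds:
        chosen = rng.choice(config.n_gene, size=min(config.genes_per_compound, config.n_gene), replace=False, p=weights)
        c_genes[c] = {genes[i] for i in chosen}
        triples.extend((c, "binds", g) for g in sorted(c_genes[c]))
    for d in diseases:
        chosen = rng.choice(config.n_gene, size=min(config.genes_per_disease, config.n_gene), replace=False, p=weights)
        d_genes[d] = {genes[i] for i in chosen}
        triples.extend((g, "associates", d) for g in sorted(d_genes[d]))
    for _ in range(config.n_gene_gene_edges):
        i, j = rng.choice(config.n_gene, size=2, replace=False)
        triples.append((genes[i], "interacts", genes[j]))
    for c in compounds:
        chosen = rng.choice(config.n_sideeffect, size=min(config.sideeffects_per_compound, config.n_sideeffect), replace=False)
        triples.extend((c, "causes", sideeffects[i]) for i in sorted(chosen))
    for d in diseases:
        chosen = rng.choice(config.n_anatomy, size=min(config.anatomies_per_disease, config.n_anatomy), replace=False)
        triples.extend((d, "localizes", anatomies[i]) for i in sorted(chosen))

    return {
        "compounds": compounds,
        "diseases": diseases,
        "genes": genes,
        "anatomies": anatomies,
        "sideeffects": sideeffects,
        "triples": triples,
        "compound_genes": c_genes,
        "disease_genes": d_genes,
    }


def _treats_probability(config: SynthConfig, shared: int) -> float:
    return config.p_high if shared >= config.shared_gene_threshold else config.p_low


def _noise_appendage(config: SynthConfig, core: dict, rng: np.random.Generator) -> list[Triple]:
    """A connected Noise-type appendage attached to the core.

    Internal spanning tree + extra random internal edges; the only edges
    touching the core go from Noise entities to attachment-type entities,
    so every path from the core into the appendage crosses a Noise entity.
    """
    if config.n_noise == 0:
        return []
    noise = _ids("N", config.n_noise)
    triples: list[Triple] = []
    for i in range(1, config.n_noise):
        j = int(rng.integers(i))
        triples.append((noise[j], "noise_link", noise[i]))
    for _ in range(config.n_noise_internal_edges):
        i, j = rng.choice(config.n_noise, size=2, replace=False)
        triples.append((noise[i], "noise_link", noise[j]))
    anchors = {
        "Compound": core["compounds"],
        "Disease": core["diseases"],
        "Gene": core["genes"],
        "Anatomy": core["anatomies"],
        "SideEffect": core["sideeffects"],
    }[config.noise_attachment_type]
    for _ in range(config.n_noise_attachments):
        n = noise[int(rng.integers(config.n_noise))]
        a = anchors[int(rng.integers(len(anchors)))]
        triples.append((n, "noise_attach", a))
    return triples


def generate(config: SynthConfig) -> KnowledgeGraph:
    """Generate one synthetic knowledge graph; deterministic given the seed."""
    if config.p_high > 0 and (config.n_compound == 0 or config.n_disease == 0):
        raise ValueError("the planted treats rule needs compounds and diseases")
    ss = np.random.SeedSequence(config.seed).spawn(3)
    core_rng, treats_rng, noise_rng = (np.random.default_rng(s) for s in ss)

    core = _core_structure(config, core_rng)
    triples = list(core["triples"])
    for c in core["compounds"]:
        for d in core["diseases"]:
            shared = len(core["compound_genes"][c] & core["disease_genes"][d])
            if treats_rng.random() < _treats_probability(config, shared):
                triples.append((c, "treats", d))
    triples.extend(_noise_appendage(config, core, noise_rng))

    entity_types: dict[str, str] = {}
    for key, t in (
        ("compounds", "Compound"), ("diseases", "Disease"), ("genes", "Gene"),
        ("anatomies", "Anatomy"), ("sideeffects", "SideEffect"),
    ):
        entity_types.update({e: t for e in core[key]})
    entity_types.update({e: NOISE_TYPE for e in _ids("N", config.n_noise)})
    return KnowledgeGraph(triples, entity_types)


def expected_properties(config: SynthConfig) -> dict:
    """Analytic expectations for the generated graph, used as test oracles.

    The expected treats count is the sum of per-pair placement
    probabilities given the (deterministically regenerated) core
    structure; its variance is the corresponding sum of Bernoulli
    variances.
    """
    core_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    core = _core_structure(config, core_rng)
    mean = 0.0
    var = 0.0
    n_qualifying = 0
    for c in core["compounds"]:
        for d in core["diseases"]:
            shared = len(core["compound_genes"][c] & core["disease_genes"][d])
            p = _treats_probability(config, shared)
            if shared >= config.shared_gene_threshold:
                n_qualifying += 1
            mean += p
            var += p * (1 - p)
    total = (
        config.n_compound + config.n_disease + config.n_gene
        + config.n_anatomy + config.n_sideeffect + config.n_noise
    )
    return {
        "expected_treats": mean,
        "treats_sd": float(np.sqrt(var)),
        "n_qualifying_pairs": n_qualifying,
        "noise_fraction": config.n_noise / total,
        "n_entities_total": total,
    }


def default_synthetic_metapaths() -> list[Metapath]:
    """Compound/Disease metapaths matching the synthetic schema (none
    traverse the Noise type)."""
    return [
        Metapath(("Compound", "Gene", "Disease")),
        Metapath(("Compound", "Gene", "Gene", "Disease")),
        Metapath(("Compound", "SideEffect", "Compound", "Gene", "Disease")),
        Metapath(("Disease", "Anatomy", "Disease", "Gene", "Compound")),
    ]
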