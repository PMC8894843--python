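# kgfilter

Task-driven metapath filtering of typed biomedical knowledge graphs for
drug-repurposing link prediction.

Biomedical knowledge graphs such as Hetionet and DRKG integrate dozens of
sources into one typed multi-relational graph: triples *(h, r, t)* over
entities *e ∈ 𝓔* with types *φ(e) ∈ 𝒯* (Compound, Disease, Gene, …).
Knowledge-graph-embedding (KGE) models trained on such graphs optimize all
relations at once, but a drug-repurposing user cares about exactly one:
*(Compound, treats, Disease)*. When the task-relevant core is a small
minority of the graph, the embeddings underfit it. `kgfilter` implements a
random-walk procedure that extracts the task-supportive subgraph before
training:

1. **Metapath walking.** A metapath *m = (t₁, …, tₙ)* is an ordered
   sequence of entity types (e.g. Compound–Gene–Disease). Walkers start at
   every entity of type *t₁* (and, reversed, of type *tₙ*) and at each step
   move to a uniformly chosen neighbor of the next required type; a walk is
   *complete* when it reaches type *tₙ* and *stopped* when it dead-ends.
2. **Domino concatenation.** Complete walks are chained end-to-start at
   shared junction entities until a target entity-length is reached,
   avoiding small disconnected fragments.
3. **Induced subgraph.** Entities appearing in at least one concatenated
   walk form 𝓔′; the filtered graph 𝒦𝒢′ keeps exactly the triples with both
   endpoints in 𝓔′. Every retained entity then lies within
   ⌊L_max/2⌋ hops of a Compound or Disease.

Around the filter, the package provides everything needed to measure its
effect: the preprocessing rules (ambiguous Compound–Disease relation
removal, treats unification, per-split inverse relations, contradiction
check), leakage-safe holdout construction *before* filtering with holdout
restriction *after* it (so both branches are evaluated on identical holdout
sets), compact numpy trainers for three KGE scorers
(TransE `−‖e_h + e_r − e_t‖`, DistMult `⟨e_h, e_r, e_t⟩`,
ComplEx `Re⟨e_h, e_r, ē_t⟩`), and type-constrained filtered ranking with

    MRR = (1/|Q|) Σᵢ 1/rankᵢ

plus a randomized-ground-truth baseline and score-distribution diagnostics.
A seeded generator of Hetionet-like graphs with planted treats structure
and an irrelevant noise portion makes the whole pipeline testable without
downloads.

## Worked example

```python
from kgfilter.workflow import run_pipeline

results = run_pipeline({
    "dataset": {"synthetic": {"seed": 1}},
    "preprocess": {"keep_relations": ["treats"]},
    "split": {"valid_fraction": 0.125, "test_fraction": 0.125, "seed": 101},
    "filter": {"starts_per_source": 30, "concat_target_length": 30,
               "n_concat_per_metapath": 300, "seed": 201},
    "train": {"model": "distmult", "dimension": 32, "epochs_max": 60,
              "seed": 301},
    "evaluate": {"which": "test"},
}, stages=["preprocess", "split", "filter", "train", "evaluate"],
   out_dir="run")

print(results["filter"]["entity_reduction"])
print(results["evaluate"]["original"]["mrr"],
      results["evaluate"]["filtered"]["mrr"])
```

On the default synthetic conditions this prints an entity reduction around
`0.60` (the filter removes the entire noise portion plus weakly connected
genes while retaining every Compound and Disease) and test MRRs around
`0.16` for the model trained on the original graph versus `0.24` for the
model trained on the filtered graph, against a random-classifier MRR of
about `0.11` — the filtered branch wins in most seeded replicates. The same
pipeline is available from the shell:

```sh
kgfilter run --config example.yaml --stages all --out run
kgfilter filter --kg triples.tsv --nodes nodes.tsv --metapaths metapaths.txt \
    --starts 1000 --concat-length 100 --n-concat 5000 --seed 1 --out filtered
```

For full-scale graphs the walker defaults are 1000 starts per source
entity, 100-entity concatenated walks and 5000 concatenated walks per
metapath. Metapath files list one comma-separated type sequence per line;
the shipped defaults are illustrative and real studies should supply their
own list.

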