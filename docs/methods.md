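# Methods

## The filtering procedure

A knowledge graph is a triple set 𝒦𝒢 ⊂ 𝓔 × 𝓡 × 𝓔 with a single type
φ(e) ∈ 𝒯 per entity. Neighborhood is direction-agnostic: (a, r, b) makes a
and b mutually adjacent, so a metapath can be traversed in either
direction; the relation label on a traversed edge is ignored — metapaths
constrain entity types only.

Given a metapath m = (t₁, …, tₙ), the walker starts at every entity of
type t₁ and steps to a uniformly drawn neighbor of the next required type
(no degree weighting, no self-avoidance); it stops early when no neighbor
of the required type exists. The procedure is repeated from every entity
of type tₙ along the reversed metapath. Complete walks from both
directions are pooled *as walked* — forward walks run t₁→tₙ and reverse
walks tₙ→t₁ — which is what makes end-to-start junctions possible when
t₁ ≠ tₙ: a forward walk ending at a disease can only be continued by a
reverse walk starting at that disease.

Concatenation draws a uniform starting walk and repeatedly appends a
uniformly drawn walk (with replacement; a walk may recur within one chain,
which the cyclic case requires) whose first entity equals the chain's last
entity, merging the junction entity. A chain is emitted at the first
length ≥ the target (so its final length is in [target, target + n − 2]);
a chain that dead-ends earlier is discarded and a fresh attempt started,
bounded by `max_concat_attempts` (default 10 × the requested number of
chains, after which the chains built so far are returned with a warning).
The retained set 𝓔′ is the union, over metapaths, of all entities
appearing in at least one concatenated walk; the filtered graph is the
induced subgraph on 𝓔′. Per-metapath walker streams are spawned from the
master seed, so each metapath's contribution is independently
reproducible. Consequences asserted by tests: every retained entity lies
within ⌊L_max/2⌋ hops of an endpoint-type entity, adding a metapath never
shrinks 𝓔′, and high-degree bridging entities are retained at least as
often as low-degree ones.

Walker defaults follow the published protocol: 1000 starts per source
entity and metapath, 100-entity concatenated walks, 5000 chains per
metapath. Desk-scale runs in the tests and the acceptance script use
30/30/300, which saturates retention on graphs of a few hundred entities
(the filter's output stabilizes well below these counts there).

## Preprocessing and validation protocol

The pipeline order is fixed and enforced: ambiguous Compound–Disease
relations are removed (anything that is not treats-like), treats-like
relations are unified under one name, validation/test holdouts are sampled
uniformly from the target relation (floor rounding, remainder in train; no
stratification), inverse relations r⁻¹ are added to each split separately
(taking splits first prevents a fact and its inverse from straddling a
split border), and only then is the filter run — on the training graph, so
the walker never sees holdout facts. After filtering, holdout triples with
a removed endpoint are dropped from *both* branches, making the holdout
sets identical; candidate ranking is additionally restricted to entities
present in both graphs. Holdout fractions default to 12.5 % each.

## Embedding models

Three scorers share one training loop: TransE −‖e_h + e_r − e_t‖₂,
DistMult Σ_k h_k r_k t_k, and ComplEx Re(Σ_k h_k r_k t̄_k) stored as 2d
reals. The loss is binary cross-entropy of sigmoid scores with k = 5
uniform head-or-tail corruptions per positive (corruptions recreating an
observed triple are resampled with bounded retries; training-time
corruption is *not* type-constrained — the type constraint applies only to
evaluation). Optimization is plain SGD with per-sample gradients
(learning-rate meaning independent of batch size), default lr 0.1, weight
decay 1e-4 on touched rows, and entity vectors projected onto the L2 ball
of radius 2 after each step — the standard stabilizer in this model
family; without it DistMult's scores grow without bound. Embeddings
initialize uniform ±√(6/2d), d = 32 by default. A margin ranking loss is
available behind `loss="margin"`. RESCAL- and ConvE-style scorers are
extension points of the scorer registry, not implemented.

Early stopping monitors validation MRR after every epoch and stops
`patience` = 3 epochs after the best one, returning the best-epoch
snapshot. Because a desk-scale epoch is only a handful of gradient steps,
patience alone would fire during the initial flat phase of the curve, so
stopping is suppressed for the first `min_epochs` = 10 epochs.

## Evaluation

One query per holdout target triple in each direction (treats and
treats⁻¹ pooled). Candidates are all entities of the true tail's type,
minus the true tail, minus every tail observed with that head and relation
anywhere (filtered setting), intersected with the evaluable set when
comparing branches. Ties take the realistic mid-rank (rounded up), which
avoids the optimistic-rank inflation known for KGE evaluation. The random
classifier keeps the model's Compound–Disease score table fixed and
permutes which pairs are true (preserving each row's count), averaging the
filtered MRR over 100 randomizations; on symmetric 4-candidate rows it
converges to H₄/4 = 25/48, which the tests check exactly. The
score-distribution diagnostic scores positive and corrupted triples in
batches of 2000, min–max scales each batch to [0, 1] (sigmoid scaling
behind a flag; a degenerate all-equal batch maps to 0.5), and reports the
Kullback–Leibler divergence between the negative and positive histogram
densities over 50 shared bins with add-one smoothing. Published entropy
figures for this diagnostic are qualitative anchors, not targets — the
underlying estimator is not recoverable, so only reproducibility and
non-negativity are asserted. Case-study ranking scores (disease, treats⁻¹,
compound) for every compound and reports ⌊N/2⌋ as the expected median
rank.

## Synthetic study conditions

The generator emulates a Hetionet-like schema: Compound, Disease, Gene,
Anatomy, SideEffect, and an irrelevant Noise type. Compounds bind 3 genes
and diseases associate with 3, drawn with Zipf-like weight (i+1)^−0.5 so a
few hub genes carry most connections, as in real interactomes; gene–gene,
compound–side-effect and disease–anatomy edges complete the core. The
planted signal: a compound treats a disease with probability 0.9 when the
two share at least one gene neighbor and 0.01 otherwise, so the task
signal routes exactly through the structures the shipped metapaths
(C–G–D, C–G–G–D, C–SE–C–G–D, D–A–D–G–C) traverse. The noise portion — 300
entities, an internal spanning tree plus 500 extra edges, attached to
compounds by 480 links — models the registry/article/identifier periphery
of real graphs: reachable only through Noise entities, untraversable by
any shipped metapath, and in direct competition with the treats signal for
the norm-bounded embedding capacity of each compound. Defaults total ~565
entities and ~1900 triples and train in about a second; at substantially
smaller sizes the holdout contains so few treats triples that per-replicate
validation MRR is dominated by sampling noise and the branch comparison is
uninformative.

What the synthetic conditions do **not** model: realistic relation
inventories (Hetionet has 24 relation types, DRKG 107), degree
distributions beyond the gene skew, multiple treats-like source relations,
and scale. Passing tests therefore demonstrate that the implementation
behaves as specified and that the filtering effect operates in the planted
regime — not that any particular effect size transfers to a specific real
graph; full-scale runs require the real datasets and the study's own
metapath lists, both supplied by the user.

`expected_properties` regenerates the core structure from the same seed
stream and returns the analytic expected treats count (sum of per-pair
Bernoulli probabilities) with its standard deviation, used as a
simulation oracle by the tests.

## Degenerate inputs and numerical notes

Duplicate triples collapse silently with a logged count; entities with no
incident triple are dropped at construction with a logged count (this also
applies to induced subgraphs, so an induced graph never contains isolated
entities). Loading fails hard on an entity without a resolvable type or a
malformed line, naming the offender. An empty candidate set ranks the true
tail first of one. Graph statistics report the direction-agnostic average
degree 2|𝒦𝒢|/|𝓔| together with the per-direction variant |𝒦𝒢|/|𝓔|, since
published degree tables do not always state their convention. Scores are
checked finite every batch and training aborts with diagnostics otherwise.

## Known limitations

No relation-typed metapaths, no learned or degree-weighted walks, no
online filtering during training. The trainer is desk-scale by design
(dense numpy, full-vocabulary gradients); for million-triple graphs an
external KGE framework should consume the filtered TSVs this package
writes.
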