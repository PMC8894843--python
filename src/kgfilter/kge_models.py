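"""Compact knowledge-graph-embedding trainer.

Three scoring functions are implemented over shared entity/relation
embedding tables:

* ``transe`` (translational): ``s(h,r,t) = -||e_h + e_r - e_t||_2``
* ``distmult`` (bilinear-diagonal): ``s(h,r,t) = sum_k e_h[k] e_r[k] e_t[k]``
* ``complex`` (complex-bilinear): ``s(h,r,t) = Re(sum_k e_h[k] e_r[k] conj(e_t[k]))``

Higher scores mean more plausible triples.  Training minimizes binary
cross-entropy of sigmoid-transformed scores of positives against k
uniformly corrupted negatives per positive (local closed-world
assumption), by plain stochastic gradient descent with hand-derived
gradients.  Early stopping monitors validation MRR and keeps the
best-epoch snapshot; training stops ``patience`` epochs after the best
epoch.  A margin ranking loss is available behind ``loss="margin"``.

RESCAL- and ConvE-style scorers are deliberate extension points: register
a scorer via ``SCORERS`` with score/gradient callables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_core import KGError, KnowledgeGraph, Triple
from .preprocess import SplitBundle

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters for embedding training.

    ``dimension`` counts complex coordinates for the complex-bilinear
    scorer (stored as 2*dimension reals).
    """

    dimension: int = 32
    epochs_max: int = 100
    batch_size: int = 256
    learning_rate: float = 0.1
    negatives_per_positive: int = 5
    patience: int = 3
    min_epochs: int = 10  # burn-in before early stopping engages
    seed: int = 0
    loss: str = "bce"  # "bce" | "margin"
    margin: float = 1.0
    l2: float = 1e-4  # weight decay on rows touched by the batch
    max_entity_norm: float = 2.0  # entity rows projected onto this L2 ball

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss not in ("bce", "margin"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainCurves:
    """Per-epoch training loss and validation MRR; ``best_epoch`` indexes
    the epoch with the maximum validation MRR."""

    train_loss: list[float] = field(default_factory=list)
    val_mrr: list[float] = field(default_factory=list)
    best_epoch: int = 0


@dataclass
class EmbeddingModel:
    """Entity/relation embedding tables plus a named scoring function."""

    scorer: str
    dimension: int
    entity_index: dict[str, int]
    relation_index: dict[str, int]
    entity_emb: np.ndarray  # (n_entities, width)
    relation_emb: np.ndarray  # (n_relations, width)

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(
            self.scorer,
            self.dimension,
            dict(self.entity_index),
            dict(self.relation_index),
            self.entity_emb.copy(),
            self.relation_emb.copy(),
        )


# -- scoring -----------------------------------------------------------


def _score_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    return -np.linalg.norm(h + r - t, axis=-1)


def _score_distmult(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sum(h * r * t, axis=-1)


def _split_complex(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = x.shape[-1] // 2
    return x[..., :d], x[..., d:]


def _score_complex(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    hr, hi = _split_complex(h)
    rr, ri = _split_complex(r)
    tr, ti = _split_complex(t)
    return np.sum((hr * rr - hi * ri) * tr + (hr * ri + hi * rr) * ti, axis=-1)


def _grads_transe(h, r, t, g):
    diff = h + r - t
    norm = np.linalg.norm(diff, axis=-1, keepdims=True)
    unit = diff / np.maximum(norm, _EPS)
    gh = -g[:, None] * unit
    return gh, gh.copy(), -gh


def _grads_distmult(h, r, t, g):
    g = g[:, None]
    return g * r * t, g * h * t, g * h * r


def _grads_complex(h, r, t, g):
    hr, hi = _split_complex(h)
    rr, ri = _split_complex(r)
    tr, ti = _split_complex(t)
    g = g[:, None]
    gh = np.concatenate([g * (rr * tr + ri * ti), g * (-ri * tr + rr * ti)], axis=-1)
    gr = np.concatenate([g * (hr * tr + hi * ti), g * (-hi * tr + hr * ti)], axis=-1)
    gt = np.concatenate([g * (hr * rr - hi * ri), g * (hr * ri + hi * rr)], axis=-1)
    return gh, gr, gt


SCORERS = {
    "transe": (_score_transe, _grads_transe, 1),
    "distmult": (_score_distmult, _grads_distmult, 1),
    "complex": (_score_complex, _grads_complex, 2),
}

#: Field-standard aliases for the scorer names.
SCORER_ALIASES = {
    "translational": "transe",
    "bilinear-diagonal": "distmult",
    "complex-bilinear": "complex",
}


def resolve_scorer(name: str) -> str:
    name = SCORER_ALIASES.get(name, name)
    if name not in SCORERS:
        raise ValueError(f"unknown scorer {name!r}; known: {sorted(SCORERS)}")
    return name


def score_batch(
    model: EmbeddingModel,
    h_idx: np.ndarray,
    r_idx: np.ndarray,
    t_idx: np.ndarray,
) -> np.ndarray:
    score_fn = SCORERS[model.scorer][0]
    return score_fn(
        model.entity_emb[h_idx], model.relation_emb[r_idx], model.entity_emb[t_idx]
    )


def score(model: EmbeddingModel, triple: Triple) -> float:
    """Score a single (head, relation, tail) triple; higher = more plausible."""
    h, r, t = triple
    try:
        hi = model.entity_index[h]
        ti = model.entity_index[t]
        ri = model.relation_index[r]
    except KeyError as exc:
        raise KGError(f"unknown entity or relation {exc.args[0]!r}") from None
    return float(
        score_batch(model, np.array([hi]), np.array([ri]), np.array([ti]))[0]
    )


# -- negative sampling -------------------------------------------------


def sample_negatives(
    batch: list[Triple],
    kg: KnowledgeGraph,
    k: int,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> list[Triple]:
    """Corrupt each positive k times by replacing head or tail (uniform
    coin) with a uniformly drawn entity.  Corruptions that reproduce an
    observed triple are resampled up to ``max_retries`` rounds, then kept
    with a debug log (local closed-world assumption)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    entities = sorted(kg.entities)
    observed = kg.triples
    out: list[Triple] = []
    for h, r, t in batch:
        for _ in range(k):
            cand = None
            for attempt in range(max_retries):
                e = entities[rng.integers(len(entities))]
                cand = (e, r, t) if rng.integers(2) == 0 else (h, r, e)
                if cand not in observed:
                    break
            else:
                logger.debug("kept observed triple as negative: %s", cand)
            out.append(cand)
    return out


def _sample_negative_indices(
    H: np.ndarray,
    R: np.ndarray,
    T: np.ndarray,
    n_entities: int,
    k: int,
    observed: set[tuple[int, int, int]],
    rng: np.random.Generator,
    max_rounds: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized index-level corruption used by the training loop."""
    nh = np.repeat(H, k)
    nr = np.repeat(R, k)
    nt = np.repeat(T, k)
    corrupt_head = rng.integers(2, size=nh.size).astype(bool)
    repl = rng.integers(n_entities, size=nh.size)
    nh = np.where(corrupt_head, repl, nh)
    nt = np.where(corrupt_head, nt, repl)
    for _ in range(max_rounds):
        bad = np.fromiter(
            ((int(a), int(b), int(c)) in observed for a, b, c in zip(nh, nr, nt)),
            dtype=bool,
            count=nh.size,
        )
        if not bad.any():
            break
        repl = rng.integers(n_entities, size=int(bad.sum()))
        side = corrupt_head[bad]
        nh[bad] = np.where(side, repl, nh[bad])
        nt[bad] = np.where(side, nt[bad], repl)
    return nh, nr, nt


# -- training ----------------------------------------------------------


def _init_model(
    scorer: str,
    entities: list[str],
    relations: list[str],
    config: TrainConfig,
    rng: np.random.Generator,
) -> EmbeddingModel:
    width = config.dimension * SCORERS[scorer][2]
    limit = np.sqrt(6.0 / (2 * config.dimension))
    return EmbeddingModel(
        scorer=scorer,
        dimension=config.dimension,
        entity_index={e: i for i, e in enumerate(entities)},
        relation_index={r: i for i, r in enumerate(relations)},
        entity_emb=rng.uniform(-limit, limit, size=(len(entities), width)),
        relation_emb=rng.uniform(-limit, limit, size=(len(relations), width)),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce_loss_and_grad(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE loss and the per-sample score gradient (sigma(s) - y).

    The gradient is per-sample (not batch-averaged) so the learning rate
    has the same meaning regardless of batch size."""
    p = _sigmoid(s)
    loss = -np.mean(y * np.log(p + _EPS) + (1 - y) * np.log(1 - p + _EPS))
    return float(loss), p - y


def train(
    model_name: str,
    splits: SplitBundle,
    config: TrainConfig,
    evaluable: set[str] | None = None,
) -> tuple[EmbeddingModel, TrainCurves]:
    """Fit an embedding model on the bundle's train split.

    After every epoch the validation MRR (type-constrained filtered
    ranking over the bundle's target relation, via the evaluation module)
    is computed; training stops ``patience`` epochs after the best
    validation MRR and the best-epoch snapshot is returned.
    """
    from . import evaluation  # deferred: evaluation also scores models

    scorer = resolve_scorer(model_name)
    if not splits.train:
        raise KGError("train split is empty")
    train_triples = sorted(splits.train)
    entities = sorted(splits.entity_types)
    relations = sorted({r for _, r, _ in splits.all_triples})
    rng = np.random.default_rng(config.seed)
    model = _init_model(scorer, entities, relations, config, rng)

    eidx, ridx = model.entity_index, model.relation_index
    H = np.array([eidx[h] for h, _, _ in train_triples])
    R = np.array([ridx[r] for _, r, _ in train_triples])
    T = np.array([eidx[t] for _, _, t in train_triples])
    observed = set(zip(H.tolist(), R.tolist(), T.tolist()))
    n = H.size
    k = config.negatives_per_positive
    score_fn, grad_fn, _ = SCORERS[scorer]

    curves = TrainCurves()
    best_mrr = -np.inf
    best_model = model.copy()
    has_validation = bool(splits.validation)

    for epoch in range(config.epochs_max):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            ph, pr, pt = H[idx], R[idx], T[idx]
            nh, nr, nt = _sample_negative_indices(
                ph, pr, pt, len(entities), k, observed, rng
            )
            bh = np.concatenate([ph, nh])
            br = np.concatenate([pr, nr])
            bt = np.concatenate([pt, nt])
            y = np.concatenate([np.ones(ph.size), np.zeros(nh.size)])
            he, re_, te = (
                model.entity_emb[bh],
                model.relation_emb[br],
                model.entity_emb[bt],
            )
            s = score_fn(he, re_, te)
            if not np.all(np.isfinite(s)):
                raise FloatingPointError(
                    f"non-finite scores at epoch {epoch}; reduce the learning rate"
                )
            if config.loss == "bce":
                loss, g = _bce_loss_and_grad(s, y)
            else:
                loss, g = _margin_loss_and_grad(s, ph.size, k, config.margin)
            gh, gr, gt = grad_fn(he, re_, te, g)
            if config.l2:
                gh += config.l2 * he
                gt += config.l2 * te
                gr += config.l2 * re_
            ent_grad = np.zeros_like(model.entity_emb)
            rel_grad = np.zeros_like(model.relation_emb)
            np.add.at(ent_grad, bh, gh)
            np.add.at(ent_grad, bt, gt)
            np.add.at(rel_grad, br, gr)
            model.entity_emb -= config.learning_rate * ent_grad
            model.relation_emb -= config.learning_rate * rel_grad
            if config.max_entity_norm:
                rows = np.unique(np.concatenate([bh, bt]))
                norms = np.linalg.norm(model.entity_emb[rows], axis=1, keepdims=True)
                scale = np.minimum(1.0, config.max_entity_norm / np.maximum(norms, _EPS))
                model.entity_emb[rows] *= scale
            epoch_loss += loss
            n_batches += 1
        curves.train_loss.append(epoch_loss / max(n_batches, 1))

        if has_validation:
            summary = evaluation.evaluate_task(
                model, None, splits, "validation", evaluable=evaluable
            )
            mrr = summary["mrr"]
        else:
            mrr = float("nan")
        curves.val_mrr.append(mrr)
        if has_validation and mrr > best_mrr:
            best_mrr = mrr
            curves.best_epoch = epoch
            best_model = model.copy()
        if (
            has_validation
            and epoch + 1 >= config.min_epochs
            and epoch - curves.best_epoch >= config.patience
        ):
            logger.info(
                "early stop at epoch %d (best epoch %d, MRR %.4f)",
                epoch, curves.best_epoch, best_mrr,
            )
            break

    if not has_validation:
        curves.best_epoch = len(curves.train_loss) - 1
        best_model = model
    return best_model, curves


def _margin_loss_and_grad(
    s: np.ndarray, n_pos: int, k: int, margin: float
) -> tuple[float, np.ndarray]:
    """Pairwise margin ranking loss: each positive against its k negatives."""
    pos = s[:n_pos]
    neg = s[n_pos:].reshape(n_pos, k)
    viol = margin - pos[:, None] + neg  # (n_pos, k)
    active = viol > 0
    loss = float(np.mean(np.maximum(viol, 0.0)))
    g = np.zeros_like(s)
    g[:n_pos] = -active.sum(axis=1) / k
    g[n_pos:] = (active / k).ravel()
    return loss, g


# -- persistence -------------------------------------------------------


def save_model(model: EmbeddingModel, out_dir: str | Path) -> None:
    """Checkpoint: entity/relation tables as TSV plus a YAML manifest."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, index, table in (
        ("entities", model.entity_index, model.entity_emb),
        ("relations", model.relation_index, model.relation_emb),
    ):
        with open(out / f"{name}.tsv", "w") as fh:
            for key in sorted(index):
                row = "\t".join(f"{v:.8g}" for v in table[index[key]])
                fh.write(f"{key}\t{row}\n")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {"scorer": model.scorer, "dimension": model.dimension,
             "n_entities": len(model.entity_index),
             "n_relations": len(model.relation_index)},
            fh,
        )


def load_model(model_dir: str | Path) -> EmbeddingModel:
    import yaml

    model_dir = Path(model_dir)
    with open(model_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    tables = {}
    indexes = {}
    for name in ("entities", "relations"):
        index: dict[str, int] = {}
        rows = []
        with open(model_dir / f"{name}.tsv") as fh:
            for i, line in enumerate(fh):
                fields = line.rstrip("\n").split("\t")
                index[fields[0]] = i
                rows.append([float(v) for v in fields[1:]])
        indexes[name] = index
        tables[name] = np.array(rows)
    return EmbeddingModel(
        scorer=manifest["scorer"],
        dimension=manifest["dimension"],
        entity_index=indexes["entities"],
        relation_index=indexes["relations"],
        entity_emb=tables["entities"],
        relation_emb=tables["relations"],
    )
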