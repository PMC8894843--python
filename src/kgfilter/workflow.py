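"""Pipeline orchestration: preprocess -> split -> filter -> train -> evaluate.

The protocol order is fixed and enforced:

1. load (or synthesize) the graph and apply the preprocessing rules;
2. take the validation/test holdouts from the target relation, then add
   inverse relations per split;
3. run metapath filtering on the *training* graph (holdouts are taken
   before filtering, so the walker never sees holdout facts);
4. restrict the holdouts to the retained entities, making the holdout
   sets of the original and the filtered branch identical;
5. train one embedding model per branch (original vs filtered training
   graph) and evaluate both on the shared holdouts, restricting
   candidates to entities present in both graphs.

Each stage writes its artifacts plus a manifest (inputs, seeds, sha256 of
outputs) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, kge_models, preprocess
from .kg_core import KnowledgeGraph, compute_stats, load_kg, write_kg, write_stats
from .kge_models import TrainConfig
from .metapath_filter import (
    FilterParams,
    Metapath,
    filter_kg,
    read_metapaths,
    write_filter_report,
)
from .preprocess import ProtocolError, SplitBundle
from .synthetic_data import SynthConfig, default_synthetic_metapaths, generate

logger = logging.getLogger(__name__)

STAGE_ORDER = ("preprocess", "split", "filter", "train", "evaluate", "diagnose")

#: minimal prerequisites within one run
_REQUIRES = {
    "preprocess": (),
    "split": ("preprocess",),
    "filter": ("preprocess", "split"),
    "train": ("preprocess", "split"),
    "evaluate": ("preprocess", "split", "train"),
    "diagnose": ("preprocess", "split", "train"),
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _branch_seed(master_seed: int, branch: str) -> int:
    tag = int.from_bytes(hashlib.sha256(branch.encode()).digest()[:2], "big")
    ss = np.random.SeedSequence([master_seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


class Pipeline:
    """Stateful runner for one experiment directory."""

    def __init__(self, config: dict, out_dir: str | Path | None = None):
        self.config = config
        self.out = Path(out_dir or config.get("output_dir", "kgfilter_run"))
        self.out.mkdir(parents=True, exist_ok=True)
        self.kg: KnowledgeGraph | None = None
        self.bundle: SplitBundle | None = None
        self.filtered_kg: KnowledgeGraph | None = None
        self.branches: dict[str, SplitBundle] = {}
        self.models: dict[str, kge_models.EmbeddingModel] = {}
        self.curves: dict[str, kge_models.TrainCurves] = {}
        self.evaluable: set[str] | None = None
        self.done: set[str] = set()
        self.results: dict = {}

    # -- helpers -------------------------------------------------------

    def _manifest(self, stage: str, inputs: dict, outputs: list[Path]) -> None:
        manifest = {
            "stage": stage,
            "inputs": inputs,
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        stage_dir = self.out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        with open(stage_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def _require(self, stage: str) -> None:
        missing = [s for s in _REQUIRES[stage] if s not in self.done]
        if missing:
            raise ProtocolError(
                f"stage {stage!r} requires {missing} to run first: the protocol "
                "takes holdouts before filtering and trains before evaluating"
            )

    def _load_graph(self) -> KnowledgeGraph:
        ds = self.config.get("dataset", {})
        if ds.get("triples"):
            return load_kg(ds["triples"], ds.get("nodes", "prefix"))
        synth = dict(ds.get("synthetic", {}))
        return generate(SynthConfig(**synth))

    def _metapaths(self) -> list[Metapath]:
        fc = self.config.get("filter", {})
        if fc.get("metapaths_file"):
            return read_metapaths(fc["metapaths_file"])
        if fc.get("metapaths"):
            return [Metapath.parse(m) for m in fc["metapaths"]]
        return default_synthetic_metapaths()

    # -- stages --------------------------------------------------------

    def stage_preprocess(self) -> None:
        pc = self.config.get("preprocess", {})
        kg = self._load_graph()
        report = {"n_entities_loaded": len(kg.entities), "n_triples_loaded": len(kg.triples)}
        if pc.get("keep_relations"):
            kg, removed = preprocess.remove_ambiguous_relations(
                kg, pc.get("head_type", "Compound"), pc.get("tail_type", "Disease"),
                set(pc["keep_relations"]),
            )
            report["n_ambiguous_removed"] = removed
        if pc.get("unify"):
            kg, deduped = preprocess.unify_relations(
                kg, set(pc["unify"]["sources"]), pc["unify"]["name"]
            )
            report["n_deduplicated"] = deduped
        if pc.get("opposed_pairs"):
            report["n_contradictions"] = preprocess.count_contradictions(
                kg, {tuple(p) for p in pc["opposed_pairs"]}
            )
        self.kg = kg
        stage_dir = self.out / "preprocess"
        stage_dir.mkdir(parents=True, exist_ok=True)
        write_kg(kg, stage_dir / "triples.tsv", stage_dir / "nodes.tsv")
        write_stats(compute_stats(kg), stage_dir / "stats.tsv", stage_dir / "type_frequency.tsv")
        self.results["preprocess"] = report
        self._manifest("preprocess", pc, list(stage_dir.glob("*.tsv")))
        self.done.add("preprocess")

    def stage_split(self) -> None:
        self._require("split")
        sc = self.config.get("split", {})
        self.bundle = preprocess.make_holdout_splits(
            self.kg,
            sc.get("target_relation", "treats"),
            sc.get("valid_fraction", 0.125),
            sc.get("test_fraction", 0.125),
            int(sc.get("seed", 0)),
        )
        stage_dir = self.out / "split"
        preprocess.write_splits(self.bundle, stage_dir)
        self.results["split"] = {
            "train": len(self.bundle.train),
            "validation": len(self.bundle.validation),
            "test": len(self.bundle.test),
        }
        self._manifest("split", sc, list(stage_dir.glob("*.tsv")))
        self.done.add("split")

    def stage_filter(self) -> None:
        self._require("filter")
        fc = self.config.get("filter", {})
        params = FilterParams(
            starts_per_source=int(fc.get("starts_per_source", 1000)),
            concat_target_length=int(fc.get("concat_target_length", 100)),
            n_concat_per_metapath=int(fc.get("n_concat_per_metapath", 5000)),
            seed=int(fc.get("seed", 0)),
        )
        # the walker sees only the training graph: holdouts are already out
        train_graph = KnowledgeGraph(self.bundle.train, self.kg.entity_types)
        self.filtered_kg, report = filter_kg(train_graph, self._metapaths(), params)
        stage_dir = self.out / "filter"
        stage_dir.mkdir(parents=True, exist_ok=True)
        write_kg(self.filtered_kg, stage_dir / "triples.tsv", stage_dir / "nodes.tsv")
        write_filter_report(report, stage_dir / "report.tsv")
        self.results["filter"] = {
            "n_entities_before": report.n_entities_before,
            "n_entities_after": report.n_entities_after,
            "n_triples_before": report.n_triples_before,
            "n_triples_after": report.n_triples_after,
            "entity_reduction": report.entity_reduction,
            "triple_reduction": report.triple_reduction,
        }
        self._manifest("filter", dataclasses.asdict(params), list(stage_dir.glob("*.tsv")))
        self.done.add("filter")

    def _branch_bundles(self) -> dict[str, SplitBundle]:
        """Per-branch bundles with shared (restricted) holdouts and inverses."""
        if self.branches:
            return self.branches
        bundle = self.bundle
        if self.filtered_kg is not None:
            retained = self.filtered_kg.entities
            self.evaluable = retained & self.kg.entities
            bundle = preprocess.restrict_holdouts(bundle, retained)
            filtered_types = {
                e: t for e, t in self.kg.entity_types.items() if e in retained
            }
            filtered_bundle = dataclasses.replace(
                bundle,
                train=set(self.filtered_kg.triples),
                entity_types=filtered_types,
            )
            self.branches = {
                "original": preprocess.add_inverses_to_bundle(bundle),
                "filtered": preprocess.add_inverses_to_bundle(filtered_bundle),
            }
        else:
            self.branches = {"original": preprocess.add_inverses_to_bundle(bundle)}
        return self.branches

    def stage_train(self) -> None:
        self._require("train")
        tc = dict(self.config.get("train", {}))
        model_name = tc.pop("model", "distmult")
        master_seed = int(tc.pop("seed", 0))
        for branch, branch_bundle in self._branch_bundles().items():
            config = TrainConfig(seed=_branch_seed(master_seed, branch), **tc)
            model, curves = kge_models.train(
                model_name, branch_bundle, config, evaluable=self.evaluable
            )
            self.models[branch] = model
            self.curves[branch] = curves
            stage_dir = self.out / "train" / branch
            kge_models.save_model(model, stage_dir)
            with open(stage_dir / "curves.tsv", "w") as fh:
                fh.write("epoch\ttrain_loss\tval_mrr\n")
                for i, (l, m) in enumerate(zip(curves.train_loss, curves.val_mrr)):
                    fh.write(f"{i}\t{l:.6g}\t{m:.6g}\n")
        self.results["train"] = {
            b: {"best_epoch": c.best_epoch, "n_epochs": len(c.train_loss),
                "best_val_mrr": c.val_mrr[c.best_epoch]}
            for b, c in self.curves.items()
        }
        outputs = [p for p in (self.out / "train").rglob("*.tsv")]
        self._manifest("train", {"model": model_name, "seed": master_seed, **tc}, outputs)
        self.done.add("train")

    def stage_evaluate(self) -> None:
        self._require("evaluate")
        ec = self.config.get("evaluate", {})
        which = ec.get("which", "test")
        n_rep = int(ec.get("baseline_repetitions", 100))
        stage_dir = self.out / "evaluate"
        stage_dir.mkdir(parents=True, exist_ok=True)
        out = {}
        for branch, model in self.models.items():
            bundle = self.branches[branch]
            summary = evaluation.evaluate_task(
                model, self.kg, bundle, which, evaluable=self.evaluable
            )
            evaluation.write_evaluation_report(
                summary,
                stage_dir / f"{branch}_{which}_ranks.tsv",
                stage_dir / f"{branch}_{which}_summary.tsv",
            )
            out[branch] = {k: summary[k] for k in ("mrr", "hits@1", "hits@3", "hits@10", "n_queries")}
            out[branch]["random_baseline"] = self._random_baseline(
                model, bundle, which, n_rep
            )
        self.results["evaluate"] = out
        self._manifest("evaluate", {"which": which}, list(stage_dir.glob("*.tsv")))
        self.done.add("evaluate")

    def _random_baseline(
        self, model, bundle: SplitBundle, which: str, n_rep: int
    ) -> float:
        """Task difficulty: the branch model's compound-disease scores
        evaluated against a randomized ground-truth adjacency."""
        target = bundle.target_relation
        truth = {
            (h, t) for h, r, t in bundle.holdout(which) if r == target
        }
        if not truth:
            return float("nan")
        head_type = self.config.get("preprocess", {}).get("head_type", "Compound")
        tail_type = self.config.get("preprocess", {}).get("tail_type", "Disease")
        heads = sorted(
            e for e, t in bundle.entity_types.items()
            if t == head_type and (self.evaluable is None or e in self.evaluable)
        )
        tails = sorted(
            e for e, t in bundle.entity_types.items()
            if t == tail_type and (self.evaluable is None or e in self.evaluable)
        )
        eidx, ridx = model.entity_index, model.relation_index
        table = {}
        r_id = ridx[target]
        t_ids = np.array([eidx[t] for t in tails])
        for h in heads:
            s = kge_models.score_batch(
                model, np.full(t_ids.size, eidx[h]), np.full(t_ids.size, r_id), t_ids
            )
            table.update({(h, t): float(v) for t, v in zip(tails, s)})
        seed = int(self.config.get("evaluate", {}).get("baseline_seed", 0))
        return evaluation.random_baseline(
            table, truth & set(table), n_rep=n_rep, rng=np.random.default_rng(seed)
        )

    def stage_diagnose(self) -> None:
        self._require("diagnose")
        dc = self.config.get("diagnose", {})
        stage_dir = self.out / "diagnose"
        stage_dir.mkdir(parents=True, exist_ok=True)
        out = {}
        for branch, model in self.models.items():
            diag = evaluation.score_distribution_diagnostic(
                model,
                self.branches[branch].train,
                n_samples=int(dc.get("n_samples", 200_000)),
                batch_size=int(dc.get("batch_size", 2000)),
                rng=np.random.default_rng(int(dc.get("seed", 0))),
            )
            np.savetxt(
                stage_dir / f"{branch}_scores.tsv",
                np.column_stack([diag.positive_scores, diag.negative_scores]),
                delimiter="\t", header="positive\tnegative", comments="",
                fmt="%.6g",
            )
            out[branch] = {"divergence": diag.divergence}
        self.results["diagnose"] = out
        self._manifest("diagnose", dc, list(stage_dir.glob("*.tsv")))
        self.done.add("diagnose")

    # -- driver --------------------------------------------------------

    def run(self, stages: str | list[str] = "all") -> dict:
        if stages == "all":
            requested = list(STAGE_ORDER)
        else:
            requested = list(stages)
        unknown = set(requested) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGE_ORDER:
            if stage in requested:
                getattr(self, f"stage_{stage}")()
        with open(self.out / "results.json", "w") as fh:
            json.dump(self.results, fh, indent=2, sort_keys=True, default=float)
        return self.results


def run_pipeline(
    config: dict | str | Path, stages: str | list[str] = "all",
    out_dir: str | Path | None = None,
) -> dict:
    """Run the pipeline described by ``config`` (a dict or a YAML path)."""
    if not isinstance(config, dict):
        config = load_config(config)
    return Pipeline(config, out_dir).run(stages)
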