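"""End-to-end orchestration: embeddings -> graph -> GCN -> report.

Optional stages: PSO hyperparameter search, dense-baseline comparison,
and a three-arm edge-strategy ablation (self-loops only / + KNN /
+ class-aware). Every artifact is stamped with the resolved-config hash
and the global seed; identical configs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from mrigcn import evaluation
from mrigcn.embeddings import CLASS_NAMES, EmbeddingTable, load_feature_table
from mrigcn.graph import GraphConfig, build_graph
from mrigcn.model import (
    TrainConfig,
    dense_baseline_train,
    init_params,
    predict,
    save_checkpoint,
    train,
)
from mrigcn.pso import SearchBounds, SwarmConfig, optimize
from mrigcn.synthetic import SyntheticConfig, make_split, sample_embeddings

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # exactly one input source
    feature_table: str | None = None
    synthetic: SyntheticConfig | None = None

    graph: GraphConfig = field(default_factory=GraphConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    hidden_dim: int = 256
    dropout_p: float = 0.3
    n_classes: int = 4
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    run_pso: bool = False
    run_baseline: bool = False
    run_ablation: bool = False
    ablation_seeds: int = 10
    out_dir: str = "run_output"
    seed: int = 42

    def __post_init__(self) -> None:
        if (self.feature_table is None) == (self.synthetic is None):
            raise ValueError("exactly one input source (feature_table or synthetic) is required")

    def resolved(self) -> dict:
        d = asdict(self)
        d.pop("out_dir", None)  # output location does not affect results
        return json.loads(json.dumps(d, default=str, sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            if "n_per_class" in syn:
                syn["n_per_class"] = tuple(syn["n_per_class"])
            if "overlap_pairs" in syn:
                syn["overlap_pairs"] = tuple(tuple(p) for p in syn["overlap_pairs"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "graph" in d and isinstance(d["graph"], dict):
            d["graph"] = GraphConfig(**d["graph"])
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = TrainConfig(**d["training"])
        if "swarm" in d and isinstance(d["swarm"], dict):
            d["swarm"] = SwarmConfig(**d["swarm"])
        return cls(**d)


def _load_table(cfg: PipelineConfig) -> EmbeddingTable:
    if cfg.synthetic is not None:
        return sample_embeddings(cfg.synthetic)
    return load_feature_table(cfg.feature_table)


def _train_and_eval(
    table: EmbeddingTable,
    masks,
    cfg: PipelineConfig,
    hidden_dim: int,
    lr: float,
    dropout_p: float,
    seed: int,
    graph_cfg: GraphConfig | None = None,
):
    train_mask, val_mask, test_mask = masks
    gcfg = graph_cfg or cfg.graph
    graph = build_graph(table.vectors, table.labels, train_mask, val_mask, test_mask, gcfg)
    params = init_params(
        table.dim, hidden_dim, cfg.n_classes, seed=seed, dropout_p=dropout_p
    )
    tc = TrainConfig(
        learning_rate=lr,
        max_epochs=cfg.training.max_epochs,
        patience=cfg.training.patience,
        batch_size=cfg.training.batch_size,
        seed=seed,
    )
    best, hist = train(graph, params, tc)
    pred, conf = predict(graph, best)
    y_true = table.labels[test_mask]
    acc = float((pred == y_true).mean())
    return graph, best, hist, pred, conf, acc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages, write artifacts, return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    manifest: dict = {"stamp": stamp, "stages": [], "artifacts": {}, "failed_stage": None}
    t0 = time.time()
    class_names = CLASS_NAMES[: cfg.n_classes]

    def stage(name):
        logger.info("stage %s starting", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        table = _load_table(cfg)
        if table.labels is None:
            raise ValueError("input table must carry labels")
        masks = make_split(table.labels, cfg.test_fraction, cfg.val_fraction, cfg.seed)

        hidden_dim, lr, dropout_p = cfg.hidden_dim, cfg.training.learning_rate, cfg.dropout_p

        if cfg.run_pso:
            stage("pso")
            graph = build_graph(
                table.vectors, table.labels, masks[0], masks[1], masks[2], cfg.graph
            )
            best_pos, best_fit, trace = optimize(
                SearchBounds(), cfg.swarm, data=graph,
                trace_path=out / "pso_trace.jsonl",
            )
            hidden_dim, lr, dropout_p = int(best_pos[0]), float(best_pos[1]), float(best_pos[2])
            manifest["artifacts"]["pso_trace"] = "pso_trace.jsonl"
            manifest["pso_best"] = {
                "hidden_dim": hidden_dim, "learning_rate": lr,
                "dropout_p": dropout_p, "fitness": best_fit,
            }

        stage("train")
        graph, params, hist, pred, conf, acc = _train_and_eval(
            table, masks, cfg, hidden_dim, lr, dropout_p, cfg.seed
        )
        hist.to_jsonl(out / "history.jsonl")
        save_checkpoint(
            params, out / "checkpoint.npz",
            meta={**stamp, "graph": asdict(cfg.graph)},
        )
        manifest["artifacts"]["history"] = "history.jsonl"
        manifest["artifacts"]["checkpoint"] = "checkpoint.npz"

        stage("evaluate")
        y_true = table.labels[masks[2]]
        cm = evaluation.confusion_matrix(
            [class_names[i] for i in y_true],
            [class_names[i] for i in pred],
            class_names,
        )
        cm.to_csv(out / "confusion.csv")
        report = evaluation.aggregate_metrics(cm)
        payload = {
            "stamp": stamp,
            "test_accuracy": acc,
            "best_val_accuracy": hist.best_val_acc,
            "stopped_epoch": hist.stopped_epoch,
            "metrics": report.presentation(),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest["artifacts"]["report"] = "report.json"
        manifest["artifacts"]["confusion"] = "confusion.csv"
        manifest["test_accuracy"] = acc

        if cfg.run_baseline:
            stage("baseline")
            comparison = compare_with_baseline(table, masks, cfg)
            (out / "comparison.json").write_text(json.dumps(comparison, indent=2, sort_keys=True))
            manifest["artifacts"]["comparison"] = "comparison.json"

        if cfg.run_ablation:
            stage("ablation")
            abl = edge_strategy_ablation(cfg, n_seeds=cfg.ablation_seeds)
            (out / "ablation.json").write_text(json.dumps(abl, indent=2, sort_keys=True))
            manifest["artifacts"]["ablation"] = "ablation.json"

    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def compare_with_baseline(table: EmbeddingTable, masks, cfg: PipelineConfig) -> dict:
    """GCN vs dense-MLP comparison on identical splits (per-class F1 + paired test)."""
    train_mask, val_mask, test_mask = masks
    class_names = CLASS_NAMES[: cfg.n_classes]
    _, _, _, pred_g, _, acc_g = _train_and_eval(
        table, masks, cfg, cfg.hidden_dim, cfg.training.learning_rate, cfg.dropout_p, cfg.seed
    )
    baseline, _ = dense_baseline_train(
        table.vectors, table.labels, train_mask, val_mask, cfg.training,
        n_classes=cfg.n_classes,
    )
    pred_b = baseline.forward(table.vectors[test_mask]).argmax(axis=1)
    y_true = table.labels[test_mask]
    acc_b = float((pred_b == y_true).mean())

    def f1s(pred):
        cm = evaluation.confusion_matrix(
            [class_names[i] for i in y_true], [class_names[i] for i in pred], class_names
        )
        rep = evaluation.aggregate_metrics(cm)
        return [m.f1 for m in rep.per_class]

    f1_g, f1_b = f1s(pred_g), f1s(pred_b)
    test = evaluation.paired_comparison(f1_g, f1_b)
    return {
        "gcn": {"test_accuracy": acc_g, "per_class_f1": f1_g},
        "dense_baseline": {"test_accuracy": acc_b, "per_class_f1": f1_b},
        "paired_t": {
            "mean_diff": test.mean_diff,
            "t_statistic": None if np.isnan(test.t_statistic) else test.t_statistic,
            "p_value": None if np.isnan(test.p_value) else test.p_value,
            "degenerate": test.degenerate,
        },
    }


def edge_strategy_ablation(cfg: PipelineConfig, n_seeds: int = 10) -> dict:
    """Three-arm ablation: self-loops only, + KNN, + class-aware edges.

    Each arm re-uses the same seeds so accuracy differences reflect edge
    strategy rather than initialization.
    """
    if cfg.synthetic is None:
        raise ValueError("ablation requires a synthetic input source")
    arms = {
        "self_loops": GraphConfig(k=cfg.graph.k, tau=cfg.graph.tau, use_knn=False,
                                  use_class_edges=False, class_edges_per_node=0,
                                  seed=cfg.graph.seed),
        "self_loops_knn": GraphConfig(k=cfg.graph.k, tau=cfg.graph.tau,
                                      use_class_edges=False, class_edges_per_node=0,
                                      seed=cfg.graph.seed),
        "self_loops_knn_class": GraphConfig(k=cfg.graph.k, tau=cfg.graph.tau,
                                            use_class_edges=True,
                                            class_edges_per_node=cfg.graph.class_edges_per_node,
                                            seed=cfg.graph.seed),
    }
    results = {name: [] for name in arms}
    for s in range(n_seeds):
        seed = cfg.seed + s
        syn = SyntheticConfig(**{**asdict(cfg.synthetic), "seed": seed,
                                 "n_per_class": tuple(cfg.synthetic.n_per_class),
                                 "overlap_pairs": tuple(map(tuple, cfg.synthetic.overlap_pairs))})
        table = sample_embeddings(syn)
        masks = make_split(table.labels, cfg.test_fraction, cfg.val_fraction, seed)
        for name, gcfg in arms.items():
            *_, acc = _train_and_eval(
                table, masks, cfg, cfg.hidden_dim, cfg.training.learning_rate,
                cfg.dropout_p, seed, graph_cfg=gcfg,
            )
            results[name].append(acc)
    return {
        name: {"per_seed": accs, "mean": float(np.mean(accs))}
        for name, accs in results.items()
    }
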