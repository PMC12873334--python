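"""Configuration, table I/O, artifact export, and the pipeline driver.

All randomness flows from one root seed that is expanded into named
per-stage streams; every artifact is stamped with a hash of the (config,
seed) pair, so identical inputs reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from . import knowledge_graph as kg
from .estimators import KGGCNLSTMForecaster
from .knowledge_graph import DrugRecord, KnowledgeGraph
from .model_core import init_model_params
from .preprocessing import (
    MIN_VALID_WEEKS,
    OUTLIER_SIGMA,
    TEST_WEEKS,
    VAL_WEEKS,
    WINDOW,
    DemandPanel,
    aggregate_weekly,
    filter_min_history,
)
from .synthetic_data import SimConfig, generate_dataset
from .training_eval import TrainConfig, run_experiment

logger = logging.getLogger("kgdemand")

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "load_tables",
    "records_from_catalog",
    "build_graph",
    "export_graph",
    "save_checkpoint",
    "load_checkpoint",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serialisable."""

    data_dir: str = "data"
    out_dir: str = "out"
    window: int = WINDOW
    min_valid_weeks: int = MIN_VALID_WEEKS
    outlier_sigma: float = OUTLIER_SIGMA
    test_weeks: int = TEST_WEEKS
    val_weeks: int = VAL_WEEKS
    hop: int = 2
    variant: str = "gcn2"
    ablation_variants: list[str] = field(
        default_factory=lambda: ["gcn2", "lstm_only", "kg_gcn_mlp", "gcn_lstm_single_node"]
    )
    targets: list[str] = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    log_level: str = "INFO"
    train: TrainConfig = field(default_factory=TrainConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("window", "min_valid_weeks", "test_weeks", "val_weeks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML config file; missing keys fall back to defaults."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides or {})
    train = TrainConfig(**raw.pop("train", {}))
    sim_kwargs = raw.pop("sim", {})
    if "outlier_multiplier" in sim_kwargs:
        sim_kwargs["outlier_multiplier"] = tuple(sim_kwargs["outlier_multiplier"])
    if "base_demand_range" in sim_kwargs:
        sim_kwargs["base_demand_range"] = tuple(sim_kwargs["base_demand_range"])
    sim = SimConfig(**sim_kwargs)
    return RunConfig(train=train, sim=sim, **raw)


def config_hash(config: RunConfig, seed: int) -> str:
    """Hash of the computation-relevant configuration plus the seed.

    Paths and logging are excluded: results depend on (config, seed) alone,
    not on where artifacts happen to live.
    """
    payload = config.to_dict()
    for incidental in ("data_dir", "out_dir", "log_level"):
        payload.pop(incidental, None)
    text = json.dumps({"config": payload, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# tables


_SCHEMAS = {
    "transactions": ["drug_id", "date", "quantity"],
    "catalog": ["drug_id", "raw_name", "item_type", "atc_code"],
    "ddi": ["drug_id_a", "drug_id_b"],
    "inn_map": ["core_name", "inn"],
    "drug_db": ["inn", "atc_code"],
}


def load_tables(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load and schema-validate every CSV present in ``data_dir``.

    Unparseable dates in the transactions table are dropped row by row and
    reported (with line numbers) in the log; a missing required column is a
    hard error naming it.
    """
    data_dir = Path(data_dir)
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in _SCHEMAS.items():
        path = data_dir / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing column(s) {missing}")
        if name == "transactions":
            df["quantity"] = pd.to_numeric(df["quantity"], errors="raise")
            parsed = pd.to_datetime(df["date"], errors="coerce")
            bad = parsed.isna()
            if bad.any():
                for line in (df.index[bad] + 2).tolist():  # +2: header and 1-basing
                    logger.warning("%s line %d: unparseable date, row dropped", path.name, line)
            df = df.loc[~bad].assign(date=parsed[~bad])
        tables[name] = df
        logger.info("%s: %d rows loaded", path.name, len(df))
    return tables


def records_from_catalog(catalog: pd.DataFrame) -> list[DrugRecord]:
    records = []
    for _, row in catalog.iterrows():
        atc = row.get("atc_code")
        atc = None if pd.isna(atc) or atc in ("", None) else str(atc)
        records.append(
            DrugRecord(
                drug_id=row["drug_id"],
                raw_name=row["raw_name"],
                core_name=kg.clean_product_name(row["raw_name"]),
                item_type=row["item_type"],
                atc_code=atc,
            )
        )
    return records


def build_graph(records: list[DrugRecord], ddi: pd.DataFrame | None) -> KnowledgeGraph:
    edges = kg.substitution_edges(records)
    if ddi is not None and not ddi.empty:
        edges += kg.combination_edges(records, ddi)
    graph = kg.assemble_graph(records, edges)
    logger.info(
        "graph: %d nodes, %d substitution + %d combination relations",
        graph.n_nodes,
        sum(kg.SUBSTITUTION in r for r in graph.relation_labels.values()),
        sum(kg.COMBINATION in r for r in graph.relation_labels.values()),
    )
    return graph


def export_graph(graph: KnowledgeGraph, out_dir: str | Path) -> None:
    """Edge-list and node-index CSVs plus a Matrix Market adjacency."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph.edge_list().to_csv(out / "edges.csv", index=False)
    pd.DataFrame({"position": range(graph.n_nodes), "drug_id": graph.node_index}).to_csv(
        out / "nodes.csv", index=False
    )
    scipy.io.mmwrite(out / "adjacency.mtx", scipy.sparse.coo_matrix(graph.adjacency))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, model: KGGCNLSTMForecaster, meta: dict | None = None) -> None:
    """Self-describing archive: config snapshot + every weight block by name."""
    params = {k: v for k, v in model.get_params().items() if k != "adjacency"}
    payload = {"params": params, "meta": meta or {}}
    arrays = {f"weight__{k}": v for k, v in model.network_.parameter_dict().items()}
    np.savez(
        path,
        config_json=np.array(json.dumps(payload, default=str)),
        a_hat=model.a_hat_,
        position=np.array(model.position_),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> KGGCNLSTMForecaster:
    """Bit-exact reconstruction of a saved estimator."""
    with np.load(path, allow_pickle=False) as data:
        payload = json.loads(str(data["config_json"]))
        arrays = {k[len("weight__"):]: data[k] for k in data.files if k.startswith("weight__")}
        a_hat = data["a_hat"]
        position = int(data["position"])
    est = KGGCNLSTMForecaster(**payload["params"])
    if est.gcn_layers > 0:
        n_features = arrays["gcn_W_0"].shape[0]
    elif est.temporal == "lstm":
        n_features = arrays["lstm_W_f"].shape[0]
    else:
        n_features = arrays["mlp_W"].shape[0]
    from .model_core import ForecastNetwork

    params = init_model_params(
        np.random.default_rng(0),
        n_features=n_features,
        gcn_layers=est.gcn_layers,
        gcn_hidden=est.gcn_hidden,
        hidden_dim=est.hidden_dim,
        temporal=est.temporal,
        dropout_rate=est.dropout,
    )
    net = ForecastNetwork(params, clip=est.clip, pool=est.pool)
    net.set_parameters(arrays)
    est.network_ = net
    est.a_hat_ = a_hat
    est.position_ = position
    est.n_features_in_ = n_features
    return est


# ---------------------------------------------------------------------------
# pipeline


def _stamp(config: RunConfig, seed: int) -> dict:
    return {"config_hash": config_hash(config, seed), "seed": seed}


def _load_panel(config: RunConfig) -> tuple[DemandPanel, KnowledgeGraph]:
    tables = load_tables(config.data_dir)
    for required in ("transactions", "catalog"):
        if required not in tables:
            raise FileNotFoundError(f"{required}.csv not found in {config.data_dir}")
    panel = aggregate_weekly(tables["transactions"])
    n_before = len(panel.drug_ids)
    panel = filter_min_history(panel, config.min_valid_weeks)
    logger.info("history filter: %d -> %d drugs", n_before, len(panel.drug_ids))
    records = records_from_catalog(tables["catalog"])
    graph = build_graph(records, tables.get("ddi"))
    return panel, graph


def run_pipeline(config: RunConfig, command: str, seed: int | None = None) -> dict:
    """Execute one pipeline stage and write its artifacts.

    Commands: simulate | build-graph | preprocess | train | evaluate | ablate.
    Returns a summary dict (also written as JSON next to the artifacts).
    """
    logging.basicConfig(level=config.log_level)
    seed = config.train.seed if seed is None else seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config, seed)

    if command == "simulate":
        sim = dataclasses.replace(config.sim, seed=seed)
        data = generate_dataset(sim)
        data_dir = Path(config.data_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
        data.transactions.to_csv(data_dir / "transactions.csv", index=False)
        pd.DataFrame(
            [
                {
                    "drug_id": r.drug_id,
                    "raw_name": r.raw_name,
                    "item_type": r.item_type,
                    "atc_code": r.atc_code or "",
                }
                for r in data.records
            ]
        ).to_csv(data_dir / "catalog.csv", index=False)
        data.ddi_pairs.to_csv(data_dir / "ddi.csv", index=False)
        data.inn_map.to_csv(data_dir / "inn_map.csv", index=False)
        data.drug_db.to_csv(data_dir / "drug_db.csv", index=False)
        truth = {
            "groups": data.truth.groups,
            "coupling_pairs": data.truth.coupling_pairs,
            **stamp,
        }
        (data_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        summary = {"command": command, "n_records": len(data.records),
                   "n_transactions": len(data.transactions), **stamp}

    elif command == "build-graph":
        tables = load_tables(config.data_dir)
        records = records_from_catalog(tables["catalog"])
        graph = build_graph(records, tables.get("ddi"))
        export_graph(graph, out)
        summary = {"command": command, "n_nodes": graph.n_nodes,
                   "n_pairs": len(graph.relation_labels), **stamp}

    elif command == "preprocess":
        panel, _ = _load_panel(config)
        panel.to_frame().to_csv(out / "panel.csv")
        from .preprocessing import chronological_split

        split = chronological_split(panel, config.test_weeks, config.val_weeks, config.window)
        (out / "split.json").write_text(
            json.dumps(
                {
                    "train_weeks": [split.train_weeks.start, split.train_weeks.stop],
                    "val_weeks": [split.val_weeks.start, split.val_weeks.stop],
                    "test_weeks": [split.test_weeks.start, split.test_weeks.stop],
                    **stamp,
                },
                indent=2,
            )
        )
        summary = {"command": command, "n_drugs": len(panel.drug_ids),
                   "n_weeks": panel.n_weeks, **stamp}

    elif command in ("train", "evaluate", "ablate"):
        panel, graph = _load_panel(config)
        targets = config.targets or [
            d for d in panel.drug_ids
            if graph.adjacency[graph.position(d)].sum() > 0
        ]
        cfg = dataclasses.replace(config.train, window=config.window, hop=config.hop)
        if command == "train":
            from .training_eval import _drug_samples, build_variant, train_model

            factory = build_variant(config.variant, cfg)
            trained = []
            for target in targets:
                regions, _ = _drug_samples(panel, graph, target, cfg, factory.sample_hop)
                model, curve = train_model(
                    factory(), regions["train"], dataclasses.replace(cfg, seed=seed), regions["val"]
                )
                save_checkpoint(out / f"model_{target}.npz", model, meta={"target": target, **stamp})
                pd.DataFrame(
                    {"epoch": range(1, len(curve) + 1), "train_loss": curve,
                     "val_loss": model.val_loss_curve_}
                ).to_csv(out / f"loss_{target}.csv", index=False)
                trained.append(target)
            summary = {"command": command, "targets": trained, **stamp}
        elif command == "evaluate":
            missing = [t for t in targets if not (out / f"model_{t}.npz").exists()]
            if missing:
                raise FileNotFoundError(f"missing checkpoint(s) for {missing}; run train first")
            from .training_eval import _drug_samples, compute_metrics

            truths, preds = [], []
            for target in targets:
                regions, inverse = _drug_samples(panel, graph, target, cfg, config.hop)
                model = load_checkpoint(out / f"model_{target}.npz")
                preds.append(inverse(model.predict(regions["test"])))
                truths.append(inverse(np.array([s.target_value for s in regions["test"]])))
            report = compute_metrics(np.concatenate(truths), np.concatenate(preds))
            metrics = {**report.as_dict(), **stamp}
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
            pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
            summary = {"command": command, **metrics}
        else:  # ablate
            rows = []
            for variant in config.ablation_variants:
                report = run_experiment(
                    panel, graph, targets, cfg, seeds=config.seeds, variant=variant
                )
                rows.append({"variant": variant, **report.as_dict(), **stamp})
            pd.DataFrame(rows).drop(columns=["per_seed"], errors="ignore").to_csv(
                out / "ablation.csv", index=False
            )
            summary = {"command": command, "variants": [r["variant"] for r in rows], **stamp}
    else:
        raise ValueError(f"unknown command {command!r}")

    (out / f"{command.replace('-', '_')}_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
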