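"""Reproducible experiment driver: config parsing, runs, and summaries.

A YAML config fully describes an experiment (method, topology size, DP and
mutual-learning settings, synthetic-data recipe, seed list).  ``run_experiment``
executes every (sweep value, seed) combination, writing a metrics CSV and a
JSON run manifest sufficient to replay the run bit-for-bit.  ``summarize``
aggregates one or more run directories into per-round mean +/- sd tables,
pooling over clients and seeds.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accountant import to_epsilon
from .data import LabelledDataset, make_synthetic, partition_dirichlet, partition_skewed
from .dp import DPConfig
from .federation import METHODS, ProtocolConfig, run_protocol
from .nn import ArchSpec
from .objectives import MutualWeights

__all__ = ["load_config", "run_experiment", "summarize"]

METRIC_COLUMNS = [
    "method", "sweep_key", "sweep_value", "seed", "round", "client", "model",
    "accuracy", "macro_accuracy", "epsilon", "dropped",
]


class ConfigError(ValueError):
    """Config schema violation, reported with the offending key path."""


def _need(d: dict, key: str, path: str):
    if key not in d:
        raise ConfigError(f"missing required config key: {path}.{key}".lstrip("."))
    return d[key]


def _arch_from_config(d: dict, input_shape, n_classes: int, path: str) -> ArchSpec:
    family = _need(d, "family", path)
    hidden = tuple(tuple(h) if isinstance(h, list) else h for h in _need(d, "hidden", path))
    try:
        return ArchSpec(family=family, input_shape=tuple(np.atleast_1d(input_shape)),
                        hidden=hidden, n_classes=n_classes)
    except ValueError as err:
        raise ConfigError(f"{path}: {err}") from err


def load_config(path: str | Path) -> dict:
    """Parse and validate an experiment config file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    method = _need(cfg, "method", "")
    if method not in METHODS:
        raise ConfigError(f"method: must be one of {METHODS}, got {method!r}")
    for key in ("rounds", "n_clients", "seeds", "data", "model"):
        _need(cfg, key, "")
    data = cfg["data"]
    for key in ("n_classes", "shape", "n_per_class", "partition"):
        _need(data, key, "data")
    part = data["partition"]
    kind = _need(part, "kind", "data.partition")
    if kind == "skewed":
        _need(part, "p_major", "data.partition")
        _need(part, "per_client_n", "data.partition")
    elif kind == "dirichlet":
        _need(part, "concentration", "data.partition")
    else:
        raise ConfigError(f"data.partition.kind: unknown kind {kind!r}")
    _need(cfg["model"], "proxy", "model")
    return cfg


def _build_protocol_config(cfg: dict, seed: int) -> ProtocolConfig:
    data = cfg["data"]
    shape = data["shape"]
    shape = (int(shape),) if np.isscalar(shape) else tuple(shape)
    n_classes = int(data["n_classes"])
    proxy_arch = _arch_from_config(cfg["model"]["proxy"], shape, n_classes, "model.proxy")
    private_arch = None
    if cfg["model"].get("private") is not None:
        priv = cfg["model"]["private"]
        if isinstance(priv, list):
            private_arch = tuple(
                _arch_from_config(p, shape, n_classes, f"model.private[{i}]")
                for i, p in enumerate(priv)
            )
        else:
            private_arch = _arch_from_config(priv, shape, n_classes, "model.private")
    mutual_cfg = cfg.get("mutual", {})
    dp_cfg = cfg.get("dp", {})
    return ProtocolConfig(
        method=cfg["method"],
        rounds=int(cfg["rounds"]),
        proxy_arch=proxy_arch,
        private_arch=private_arch,
        mutual=MutualWeights(
            float(mutual_cfg.get("alpha", 0.5)), float(mutual_cfg.get("beta", 0.5))
        ),
        dp=DPConfig(
            clip_C=float(dp_cfg.get("clip_C", 1.0)),
            sigma=float(dp_cfg.get("sigma", 1.0)),
        ),
        lr=float(cfg.get("lr", 0.001)),
        rule=cfg.get("rule", "adam"),
        weight_decay=float(cfg.get("weight_decay", 0.0)),
        batch_size=int(cfg.get("batch_size", 32)),
        seed=seed,
        delta=float(cfg.get("delta", 1e-5)),
        budget_epsilon=cfg.get("budget_epsilon"),
        local_steps=cfg.get("local_steps"),
    )


def _build_data(
    cfg: dict, seed: int
) -> tuple[list[LabelledDataset], LabelledDataset]:
    """Pooled synthetic data split into an IID test set and client partitions."""
    data = cfg["data"]
    n_classes = int(data["n_classes"])
    test_per_class = int(data.get("test_per_class", 100))
    pool = make_synthetic(
        n_classes=n_classes,
        shape=data["shape"],
        n_per_class=int(data["n_per_class"]) + test_per_class,
        class_separation=float(data.get("class_separation", 3.0)),
        noise_sd=float(data.get("noise_sd", 1.0)),
        seed=seed,
    )
    n_test = test_per_class * n_classes
    test_set = pool.subset(np.arange(n_test))  # pool is pre-shuffled: IID split
    train_pool = pool.subset(np.arange(n_test, len(pool)))
    K = int(cfg["n_clients"])
    part = data["partition"]
    if part["kind"] == "skewed":
        plan = partition_skewed(
            train_pool, K, float(part["p_major"]), int(part["per_client_n"]), seed=seed
        )
    else:
        plan = partition_dirichlet(train_pool, K, float(part["concentration"]), seed=seed)
    return [train_pool.subset(a) for a in plan.assignments], test_set


def _set_path(cfg: dict, dotted: str, value) -> None:
    keys = dotted.split(".")
    d = cfg
    for k in keys[:-1]:
        d = d[k]
    d[keys[-1]] = value


def run_experiment(config_path: str | Path, out_dir: str | Path) -> dict:
    """Execute a config (all sweep values x all seeds); write CSV + manifest.

    Returns the manifest.  Artifacts: ``metrics.csv`` (one row per round,
    client, and model) and ``manifest.json`` (config snapshot, seeds, final
    metrics, per-client privacy reports, version stamp).
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sweep = cfg.get("sweep") or {None: [None]}
    if len(sweep) > 1:
        raise ConfigError("sweep: at most one swept parameter is supported")
    (sweep_key, sweep_values), = sweep.items()

    frames = []
    reports = []
    for value in sweep_values:
        run_cfg = json.loads(json.dumps(cfg))  # deep copy
        run_cfg.pop("sweep", None)
        if sweep_key is not None:
            _set_path(run_cfg, sweep_key, value)
        for seed in cfg["seeds"]:
            pconfig = _build_protocol_config(run_cfg, int(seed))
            datasets, test_set = _build_data(run_cfg, int(seed))
            metrics, clients = run_protocol(pconfig, datasets, test_set)
            metrics.insert(0, "method", cfg["method"])
            metrics.insert(1, "sweep_key", sweep_key or "")
            metrics.insert(2, "sweep_value", value if value is not None else "")
            metrics.insert(3, "seed", int(seed))
            frames.append(metrics)
            for c in clients:
                rep = to_epsilon(c.accountant, pconfig.delta) if c.accountant.steps else None
                reports.append(
                    {
                        "sweep_value": value,
                        "seed": int(seed),
                        "client": c.id,
                        "n_examples": len(c.dataset),
                        "dp_steps": c.accountant.steps,
                        "epsilon": rep.epsilon if rep else 0.0,
                        "optimal_order": rep.optimal_order if rep else None,
                        "dropped": c.dropped,
                    }
                )
    all_metrics = pd.concat(frames, ignore_index=True)[METRIC_COLUMNS]
    all_metrics.to_csv(out / "metrics.csv", index=False)

    final_round = int(all_metrics["round"].max())
    final = all_metrics[all_metrics["round"] == final_round]
    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": [int(s) for s in cfg["seeds"]],
        "final_round": final_round,
        "final_metrics": final.to_dict(orient="records"),
        "privacy_reports": reports,
        "metrics_csv": "metrics.csv",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest


def summarize(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Mean +/- sd per method, model, and round, pooled over clients and seeds.

    Rejects run directories whose configs disagree on the experiment
    structure (data recipe or topology size).
    """
    if not run_dirs:
        raise ValueError("at least one run directory is required")
    frames = []
    structure = None
    for d in run_dirs:
        manifest = json.loads((Path(d) / "manifest.json").read_text())
        sig = json.dumps(
            {k: manifest["config"].get(k) for k in ("data", "n_clients", "rounds")},
            sort_keys=True,
        )
        if structure is None:
            structure = sig
        elif sig != structure:
            raise ValueError(f"run {d} has a mismatched config (data/n_clients/rounds)")
        frames.append(pd.read_csv(Path(d) / "metrics.csv"))
    df = pd.concat(frames, ignore_index=True)
    grouped = (
        df.groupby(["method", "sweep_value", "model", "round"], dropna=False)["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd", "count": "n"})
    )
    grouped["accuracy_sd"] = grouped["accuracy_sd"].fillna(0.0)
    return grouped
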