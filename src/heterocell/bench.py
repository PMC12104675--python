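"""Train/test splits, multi-seed training, and homophily-stratified reporting.

Two split protocols are supported: the Planetoid convention (a small fixed
number of labeled cells per class — 10 per class, hence 140 on a 14-type
dataset — with 1,000 held-out test cells) and a stratified 80/20 split.
Every model x dataset combination is trained across many seeds; per-run
seeds are derived from the master seed by hashing the (dataset, model, run)
key, so adding a model or dataset never shifts another run's random stream.
Failed runs (non-finite loss) are recorded, excluded from medians.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .ccc_graph import CellGraph, PlanetoidBundle, to_planetoid
from .models import GraphOperators, ModelConfig, build_model, softmax

__all__ = [
    "SplitSpec",
    "BenchmarkReport",
    "planetoid_split",
    "fraction_split",
    "train_and_eval",
    "run_benchmark",
    "derive_seed",
]


@dataclass
class SplitSpec:
    train_indices: np.ndarray
    test_indices: np.ndarray
    protocol: str
    per_class: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.train_indices = np.asarray(self.train_indices, dtype=np.int64)
        self.test_indices = np.asarray(self.test_indices, dtype=np.int64)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


def planetoid_split(
    labels, per_class: int = 10, n_test: int = 1000, seed: int = 0
) -> SplitSpec:
    """Sample `per_class` labeled training nodes per class, then `n_test`
    test nodes from the remainder (clipped with a warning if too few)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if members.size < per_class:
            raise ValueError(
                f"class {c!r} has {members.size} members, fewer than per_class={per_class}"
            )
        train.append(rng.choice(members, size=per_class, replace=False))
    train = np.sort(np.concatenate(train))
    pool = np.setdiff1d(np.arange(labels.size), train)
    if n_test > pool.size:
        warnings.warn(
            f"n_test={n_test} exceeds {pool.size} remaining nodes; clipping"
        )
        n_test = pool.size
    test = np.sort(rng.choice(pool, size=n_test, replace=False))
    return SplitSpec(train, test, "planetoid", per_class=per_class, seed=seed)


def fraction_split(labels, train_fraction: float = 0.8, seed: int = 0) -> SplitSpec:
    """Stratified train/test split at the given training fraction."""
    labels = np.asarray(labels)
    if labels.size < 5:
        raise ValueError("need at least 5 nodes for a fraction split")
    rng = np.random.default_rng(seed)
    train = []
    for c in np.unique(labels):
        members = rng.permutation(np.where(labels == c)[0])
        k = int(round(train_fraction * members.size))
        train.append(members[:k])
    train = np.sort(np.concatenate(train))
    test = np.setdiff1d(np.arange(labels.size), train)
    return SplitSpec(train, test, "fraction_80_20", seed=seed)


def derive_seed(master_seed: int, dataset_id: str, model_name: str, run: int) -> int:
    """Stable per-run seed; independent of which other runs exist."""
    key = f"{master_seed}:{dataset_id}:{model_name}:{run}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _bundle_arrays(bundle: PlanetoidBundle, split: SplitSpec | None):
    feats, labels, edges, train_idx, test_idx = bundle.to_arrays()
    if split is not None:
        train_idx, test_idx = split.train_indices, split.test_indices
    return feats, labels, edges, train_idx, test_idx


def train_and_eval(
    model_cfg: ModelConfig,
    bundle: PlanetoidBundle,
    split: SplitSpec | None = None,
    seed: int | None = None,
    ops: GraphOperators | None = None,
) -> dict:
    """Train one model on one bundle and report test accuracy.

    The split defaults to the one encoded in the bundle (training rows
    first, test rows at `test_index`). Divergence (non-finite loss) aborts
    the run and is reported with status 'failed' rather than raised.
    """
    feats, labels, edges, train_idx, test_idx = _bundle_arrays(bundle, split)
    if seed is not None:
        model_cfg = ModelConfig(**{**model_cfg.__dict__, "seed": seed})
    n_classes = int(labels.max()) + 1
    if ops is None:
        ops = GraphOperators.from_edges(feats.shape[0], edges, hops=model_cfg.hops)
    model = build_model(model_cfg, feats.shape[1], n_classes, ops)
    opt = Adam(model.params, lr=model_cfg.learning_rate, weight_decay=model_cfg.weight_decay)
    rng = np.random.default_rng(model_cfg.seed + 1)
    Xt = Tensor(feats)

    status = "ok"
    for _ in range(model_cfg.epochs):
        if model.name == "GBKGNN":
            out = model.forward(Xt, rng, training=True, return_gates=True)
        else:
            out = model.forward(Xt, rng, training=True)
        loss = model.loss(out, labels, train_idx)
        if not np.isfinite(loss.data):
            status = "failed"
            break
        opt.zero_grad()
        loss.backward()
        opt.step()

    if status == "ok":
        out = model.forward(Xt, training=False)
        logits = out[0] if isinstance(out, tuple) else out
        pred = np.argmax(softmax(logits.data), axis=1)
        acc = float(np.mean(pred[test_idx] == labels[test_idx]))
    else:
        acc = float("nan")
    return {
        "model": model_cfg.model_name,
        "seed": model_cfg.seed,
        "accuracy": acc,
        "status": status,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
    }


@dataclass
class BenchmarkReport:
    """Tidy per-run records plus box-summary statistics."""

    records: pd.DataFrame
    summaries: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.summaries = self._summarize()

    def _summarize(self) -> pd.DataFrame:
        ok = self.records[self.records["status"] == "ok"]
        rows = []
        for (ds, model), grp in sorted(ok.groupby(["dataset", "model"])):
            a = grp["accuracy"].to_numpy()
            q1, med, q3 = np.percentile(a, [25, 50, 75])
            rows.append(
                {
                    "dataset": ds,
                    "h_ratio": grp["h_ratio"].iloc[0],
                    "model": model,
                    "n_runs": len(grp),
                    "n_failed": int(
                        (self.records.query("dataset == @ds and model == @model")[
                            "status"
                        ] != "ok").sum()
                    ),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "iqr": q3 - q1,
                }
            )
        return pd.DataFrame(rows)

    def median(self, dataset: str, model: str) -> float:
        row = self.summaries.query("dataset == @dataset and model == @model")
        return float(row["median"].iloc[0])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_benchmark(
    datasets: dict[str, CellGraph],
    models,
    n_seeds: int = 30,
    master_seed: int = 0,
    split_protocol: str = "planetoid",
    per_class: int = 10,
    n_test: int = 1000,
    epochs: int | None = None,
) -> BenchmarkReport:
    """Full factorial sweep: every model on every dataset across `n_seeds`.

    `models` is a list of names or ModelConfig instances. Each run draws a
    fresh split and fresh parameters from its derived seed. Records come out
    in a fixed sorted order regardless of execution order.
    """
    if not datasets or not len(models):
        raise ValueError("need at least one dataset and one model")
    configs = [
        m if isinstance(m, ModelConfig) else ModelConfig.for_model(m) for m in models
    ]
    if epochs is not None:
        configs = [
            ModelConfig(**{**c.__dict__, "epochs": epochs}) for c in configs
        ]
    records = []
    for ds_name in sorted(datasets):
        graph = datasets[ds_name]
        h = graph.homophily
        for cfg in configs:
            for run in range(n_seeds):
                seed = derive_seed(master_seed, ds_name, cfg.model_name, run)
                if split_protocol == "planetoid":
                    split = planetoid_split(
                        graph.y, per_class=per_class, n_test=n_test, seed=seed
                    )
                else:
                    split = fraction_split(graph.y, seed=seed)
                bundle = to_planetoid(graph, split)
                # the bundle re-indexes nodes: train first, then rest, then test
                n = graph.n_nodes
                new_split = SplitSpec(
                    np.arange(len(split.train_indices)),
                    np.asarray(bundle.test_index),
                    split.protocol,
                )
                rec = train_and_eval(cfg, bundle, new_split, seed=seed)
                rec.update({"dataset": ds_name, "h_ratio": h, "run": run})
                records.append(rec)
    df = pd.DataFrame.from_records(records).sort_values(
        ["dataset", "model", "run"], kind="stable"
    )
    cols = [
        "dataset", "h_ratio", "model", "run", "seed", "accuracy", "status",
        "n_train", "n_test",
    ]
    return BenchmarkReport(records=df[cols].reset_index(drop=True))
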