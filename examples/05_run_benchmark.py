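"""Multi-seed benchmark of several models across two homophily regimes,
with per-model median accuracy and interquartile range."""

from heterocell import ModelConfig, benchmark_graph, run_benchmark

datasets = {
    "heterophilic": benchmark_graph(0.15, n_cells=400, n_types=6, seed=4),
    "homophilic": benchmark_graph(0.85, n_cells=400, n_types=6, seed=5),
}
models = [ModelConfig.for_model(m, epochs=200) for m in ("MLP", "GCN", "GBKGNN")]

report = run_benchmark(datasets, models, n_seeds=3, master_seed=0, n_test=200)
print(report.summaries[["dataset", "h_ratio", "model", "median", "iqr", "n_runs"]]
      .to_string(index=False))
# Expected pattern: GCN trails on the heterophilic graph and recovers on the
# homophilic one; the gated bi-kernel model is strong in both regimes.
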