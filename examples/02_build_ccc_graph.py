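"""Build cell-cell communication graphs from ligand-receptor co-expression
and show how the designed signaling structure controls edge homophily:
types signaling to themselves give a homophilic graph, types signaling only
to other types a heterophilic one."""

import numpy as np

from heterocell import (
    SimulationConfig,
    build_ccc_graph,
    preprocess_pipeline,
    simulate_dataset,
)

n_types = 6
for name, design in [
    ("self-signaling (identity design)", np.eye(n_types)),
    ("cross-signaling (off-diagonal design)", 1 - np.eye(n_types)),
]:
    cfg = SimulationConfig(
        n_cells=500, n_genes=1000, n_types=n_types, n_lr_pairs=18,
        communication_design=design, seed=1,
    )
    ds = simulate_dataset(cfg)
    expr, _ = preprocess_pipeline(ds.counts, n_top_genes=300, min_cells=3)
    graph = build_ccc_graph(expr, ds.lr_pairs, T=0.0, keep_fraction=0.10)
    print(f"{name}:")
    print(f"  {graph.n_nodes} cells, {graph.n_edges} edges, "
          f"edge homophily H = {graph.homophily:.3f}, "
          f"min degree {graph.degrees().min()}")
# H near 1 means edges mostly join cells of the same type; near 0, different
# types — the regime that decides which GNN architecture is appropriate.
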