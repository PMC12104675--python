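# heterocell

Cell-type prediction on single-cell RNA-seq data is usually framed as a
feature-classification problem, but cells also talk to each other: a sender
cell expressing a ligand and a receiver expressing the cognate receptor form
a putative signaling link. `heterocell` turns this intuition into a complete,
tested analysis loop for computational biologists studying cell-cell
communication (CCC) and graph neural networks:

1. **Simulate** droplet-style UMI count matrices (negative-binomial counts,
   skewed cell-type abundances, marker genes, mitochondrial genes, implanted
   ligand-receptor programs), so every downstream stage is testable without
   any download.
2. **Preprocess** with the standard recipe: remove cells with more than a
   count ceiling (doublet-suggestive) or more than 5% mitochondrial reads,
   drop genes detected in fewer than a minimum number of cells, normalize to
   log counts-per-million, and keep the top highly variable genes.
3. **Build the CCC graph**: for every ordered pair of cells *(s, j)* score

   `W[s, j] = Σ_i  L[i, s] · R[i, j]`

   where `L[i, s] = 1` if cell *s* expresses the ligand of pair *i* above a
   threshold *T*, and `R[i, j] = 1` if cell *j* expresses **all** subunits of
   the receptor (complexes written `GENEA_GENEB`). `W` is normalized by its
   global maximum, cut to the top-weighted interactions, repaired so no cell
   is isolated, and symmetrized into an undirected cell graph.
4. **Measure edge homophily**, `H = |{(u,v) ∈ E : y_u = y_v}| / |E|` — the
   fraction of edges joining cells of the same annotated type. CCC graphs are
   often strongly *heterophilic* (low `H`): signaling happens between
   different cell types.
5. **Benchmark node classifiers** over many seeds: an MLP, four
   homophily-assuming GNNs (GCN, GraphSAGE, GAT, MixHop), and two
   heterophily-aware architectures — H2GCN (ego/neighbor separation,
   exact 1- and 2-hop aggregation, concatenation of all rounds) and GBK-GNN
   (bi-kernel messages `α_ij W_s z_j + (1-α_ij) W_d z_j` with a learned
   sigmoid gate supervised on training-edge label agreement).

The GNNs are implemented on a small reverse-mode autodiff engine over numpy
(`heterocell.autodiff`), so the package has no deep-learning framework
dependency; gradients are verified against numeric differentiation in the
test suite.

## Worked example

```python
import numpy as np
from heterocell import (SimulationConfig, simulate_dataset,
                        preprocess_pipeline, build_ccc_graph)

n_types = 6
cfg = SimulationConfig(n_cells=500, n_genes=1000, n_types=n_types,
                       n_lr_pairs=18, communication_design=np.eye(n_types),
                       seed=1)
ds = simulate_dataset(cfg)
expr, _ = preprocess_pipeline(ds.counts, n_top_genes=300, min_cells=3)
graph = build_ccc_graph(expr, ds.lr_pairs, T=0.0, keep_fraction=0.10)
print(graph.n_nodes, graph.n_edges, round(graph.homophily, 3))
```

prints `471 21226 1.0`: with an identity communication design (each type
signals only to itself) the 471 QC-surviving cells form a graph whose 21,226
edges all join same-type cells (`H = 1.0`). Swapping in the off-diagonal
design `1 - np.eye(n_types)` yields `H = 0.054` — a strongly heterophilic
graph from the same pipeline. On such a graph (see
`examples/04_train_single_model.py`) a GCN reaches 0.333 test accuracy while
the gated bi-kernel model reaches 0.627 from identical features and split.

The `examples/` directory walks through each capability: simulation and QC,
graph construction, homophily-targeted graph generation, single-model
training, and the multi-seed benchmark with median/IQR summaries.

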