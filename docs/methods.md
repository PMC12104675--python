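# Methods

## Scope and shape

`heterocell` is a library: the importable API plus the narrative scripts in
`examples/` are its interface. The pipeline stages (simulation,
preprocessing, graph construction, benchmarking) are plain functions that
read and write standard text formats (Matrix Market counts with TSV
sidecars, CSV label and ligand-receptor tables, edge-list TSV, and a
directory-of-text-files serialization of the eight-field Planetoid bundle),
so shell use is a one-line `python -c` away; no console entry point is
installed.

## Synthetic data model

The generator emulates droplet scRNA-seq of a tissue with a moderate number
of discrete cell types (default 14, as in pancreatic islets):

- **Type abundances** follow a geometric decay (`p_k ∝ 0.82^k`), giving the
  skew typical of real annotations. All proportions must be positive and sum
  to one.
- **Counts** are gamma-Poisson: gene base means are log-normal
  (`σ_log = 1.3`), each cell's library size is log-normal around
  `library_size_mean` (default 2,500 UMIs, CV 0.3, both configurable), and
  counts are drawn with dispersion `φ` in `Var = μ + φμ²` (default 0.3;
  `φ → 0` recovers Poisson *conditional on fixed library size*, which is how
  the Poisson-limit test is phrased).
- **Markers**: each type owns a 10-gene block whose mean is multiplied by
  `exp(marker_logfc)` (default 1.2 natural-log units), so feature-based
  classification is possible but not trivial.
- **Mitochondrial genes**: a small gene set (0.5% of genes, ≥ 3) is renamed
  with the `MT-` prefix and rescaled so its expected share of the library is
  3%; negative-binomial noise then puts a realistic minority of cells past
  the 5% QC cutoff.
- **Ligand-receptor programs**: active entries of the `communication_design`
  matrix (sender type → receiver type) are assigned L-R pairs round-robin.
  Ligand genes are drawn at mean 6 counts in sender-type cells and 0.02
  elsewhere, receptor subunit genes likewise in receiver-type cells, so
  binarizing at detection recovers the program (≥ 0.8 positive frequency in
  the designed type, ≤ 0.2 elsewhere). A configurable fraction of receptors
  (default 25%) has two subunits, encoded `GENEA_GENEB`.

What the generator does **not** emulate: ambient RNA, doublets as a
mechanistic process, UMI collapse, batch effects, or continuous/overlapping
cell states. Passing tests therefore demonstrate correctness of the
algorithms under a clean discrete-type model, not robustness to every real
artifact.

## Graph construction

Scoring is the binarized ligand-receptor count described in the README. The
design choices where the procedure is genuinely open:

- **Detection threshold** `T = 0` on log-CPM values (any detection),
  configurable.
- **Top-weight cut**: keep the top 10% of *nonzero* normalized scores
  (`keep_fraction = 0.10`). The cut value is the weight ranked
  `ceil(keep_fraction · k)` among the `k` nonzero entries and boundary ties
  are kept, making the result independent of sort order. Real CCC graphs are
  dense, so the default cut is deliberately mild.
- **Self-communication** (the diagonal of `W`) is excluded before
  normalization.
- **Connectivity repair** scans cells in index order; a cell with no
  surviving incoming or outgoing weight is linked to its strongest
  pre-threshold partner (global strongest cell if its raw row is empty), at
  the minimum surviving weight. Earlier repairs can un-isolate later cells —
  the scan is sequential by design, and the naive reference implementation
  in the tests enforces exactly this semantics.
- **Symmetrization by union** after thresholding: the undirected edge
  `{i, j}` exists if either directed score survives.

Edge homophily is the fraction of undirected edges whose endpoints share a
label, each edge counted once; it is undefined (an error) on an empty edge
set.

The homophily-*targeted* generator used for benchmarking places
`round(H · m)` within-class and the rest cross-class edges by rejection
sampling of distinct pairs, wires in any isolated node preferring the
underrepresented edge kind, and finishes with a degree-safe swap pass; the
realized ratio is guaranteed within ±0.02 of the target or the call fails.
Cross-class edges are uniform over unlike pairs by default; an optional
`cross_design` biases them toward designated class pairs. The default is
uniform because structured cross edges make the graph structure itself
informative enough that even homophily-assuming models succeed, which is not
the heterophilic regime of interest.

## Models

All seven classifiers run on a minimal reverse-mode autodiff engine over
numpy (dense/sparse matmul, gather/segment-sum for edge-wise message
passing, fused softmax-cross-entropy and BCE-with-logits). Parameters are
initialized uniform fan-in (`U(±1/√fan_in)`), seeded; training is
full-batch Adam with classic L2 weight decay.

- **MLP**: two layers, ReLU, dropout; ignores the graph.
- **GCN**: two rounds of `D̃^{-1/2}(A+I)D̃^{-1/2}` propagation.
- **GraphSAGE**: mean neighbor aggregation concatenated with the ego
  embedding, two layers.
- **GAT**: additive attention with 8 heads (concatenated) in the hidden
  layer, one head out, LeakyReLU(0.2) scores, softmax over incoming edges
  including self-loops.
- **MixHop**: per layer, concatenation of powers {0, 1, 2} of the normalized
  adjacency applied to separate linear maps; dropout 0.7.
- **H2GCN**: initial projection `r⁰ = ReLU(X W_e)`; each round concatenates
  degree-normalized means over the exact-distance 1-hop and 2-hop sets (ego
  embedding never averaged in, no intermediate nonlinearity); the classifier
  sees the concatenation of all rounds. Empty hop sets contribute zeros.
- **GBK-GNN**: two gated bi-kernel layers,
  `z'_i = σ(W_f z_i + |N(i)|^{-1} Σ_j [α_ij W_s z_j + (1-α_ij) W_d z_j])`,
  with `α_ij` the sigmoid of a two-layer perceptron on `[z_i, z_j]`
  (hidden width 16). σ is ReLU between layers and identity before softmax.
  The objective adds `λ` (default 1.0) times the per-layer binary
  cross-entropy of the gate against the same-label indicator, evaluated only
  on edges whose *both* endpoints are training nodes, to avoid label
  leakage.

Default hyperparameters: hidden width 64, 2 layers, dropout 0.5 (0.7 for
MixHop), learning rate 0.01 (0.001 for GBK-GNN), weight decay 5·10⁻⁴.
Epoch defaults are convergence-based at the package's problem sizes: 300,
and 400 for GBK-GNN whose learning rate is ten times smaller; both are
configurable up to the thousands.

## Benchmark protocol

Splits follow either the fixed-label-budget convention (10 labeled cells
per class — 140 on a 14-type dataset — and 1,000 test cells, clipped with a
warning when fewer remain) or a stratified 80/20 split. Graphs plus splits
are exported as Planetoid bundles (`x, y, allx, ally, tx, ty, graph,
test.index`); nodes are re-indexed so training rows come first and test
nodes occupy the trailing indices listed in `test.index`.

Per-run seeds derive from the master seed by CRC-32 of the
`(master, dataset, model, run)` key, so adding a model or dataset never
shifts another run's stream and the full report is bit-reproducible. Runs
with non-finite loss are recorded as failed and excluded from medians but
kept visible in the report. Summaries are median and quartiles per
model × dataset.

The standard benchmark condition (`simulate.benchmark_graph`) is 800 cells,
8 types, homophily-targeted edges at average degree 10, and 32-dimensional
Gaussian class-profile features (type mean scaled 0.5, unit noise) standing
in for a reduced expression profile — informative enough that an MLP is a
serious baseline, noisy enough that graph models can help or hurt. This is
an order of magnitude below tissue-scale datasets, chosen so the whole
multi-seed benchmark runs in minutes on one CPU; the qualitative ranking
(gated bi-kernel model best at low H, homophily-assuming GNNs recovering at
high H) is the object of the acceptance checks, not the absolute accuracy
values.

## Numerical and degenerate-input choices

- Binarization treats a missing ligand gene, or a receptor with any missing
  subunit, as an all-zero indicator row rather than an error.
- An all-zero score matrix passes through normalization unchanged with a
  warning; a single-cell matrix makes connectivity repair a no-op.
- HVG selection ranks by mean-binned normalized dispersion computed on
  de-logged values (20 equal-width bins on log mean); bins with fewer than
  two genes or zero spread fall back to a global z-score so a lone
  high-dispersion gene is not zeroed out. Ties, and genes with undefined
  dispersion (zero mean, ranked last), break by input gene order.
- QC thresholds are strict inequalities on the removal side: a cell at
  exactly the count ceiling or exactly 5% mitochondrial fraction survives;
  a gene detected in exactly `min_cells` cells survives.
- Sigmoid/exp inputs are clipped (±60 / ±700) for overflow safety; the BCE
  loss is computed in log-sum-exp form.

## Known limitations

- The LIANA-style consensus scoring of curated L-R resources (aggregate
  ranks, permutation p-values) is out of scope; the graph builder accepts
  any pair table and leaves its provenance to the caller.
- Published QC narratives are not always arithmetically self-consistent
  (e.g., removing 31 of 1,937 cells but keeping 1,922); the pipeline applies
  its stated rules and reports exact in/out counts rather than trying to
  reproduce any particular historical tally.
- Training is full-batch and CPU-bound; graphs beyond ~10⁴ nodes or
  ~10⁶ edges will be slow, and the GAT/GBK edge-wise layers dominate cost.
- Accuracy is measured on the test set only, with no validation-based early
  stopping, matching the single-accuracy-per-run reporting convention of
  transductive benchmarks.
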