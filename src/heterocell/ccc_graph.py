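"""Cell-cell communication graphs from ligand-receptor co-expression.

The construction scores every ordered cell pair (s, j) by the number of
ligand-receptor pairs for which the sender cell s expresses the ligand and
the receiver cell j expresses the receptor (all subunits, for multi-subunit
receptor complexes) above a detection threshold ``T``. The score matrix is
normalized to [0, 1], cut to the top-weighted interactions, repaired so no
cell is left isolated, and symmetrized into an undirected cell graph whose
edge homophily ratio — the fraction of edges joining cells of the same
annotated type — is the quantity the downstream benchmarks stratify on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CellGraph",
    "PlanetoidBundle",
    "parse_receptor",
    "binarize_ligands",
    "binarize_receptors",
    "score_interactions",
    "normalize_and_threshold",
    "ensure_connectivity",
    "build_ccc_graph",
    "edge_homophily",
    "to_planetoid",
    "edges_from_dense",
]


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------


@dataclass
class CellGraph:
    """Undirected labeled cell graph.

    Attributes
    ----------
    edges : (m, 2) int array, each row (u, v) with u < v, unique; no self-loops.
    y : (n,) int array of cell-type codes.
    X : optional (n, d) node feature matrix (typically log-CPM of HVGs).
    label_names : optional list mapping codes to type names.
    """

    n_nodes: int
    edges: np.ndarray
    y: np.ndarray
    X: np.ndarray | None = None
    label_names: list[str] | None = None
    _h: float | None = field(default=None, repr=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.y = np.asarray(self.y)
        if len(self.y) != self.n_nodes:
            raise ValueError("label vector length must equal n_nodes")
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
            hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
            canon = np.unique(np.stack([lo, hi], axis=1), axis=0)
            self.edges = canon

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def homophily(self) -> float:
        if self._h is None:
            self._h = edge_homophily(self.edges, self.y)
        return self._h

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def neighbor_dict(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for u, v in self.edges:
            adj[int(u)].append(int(v))
            adj[int(v)].append(int(u))
        return {k: sorted(v) for k, v in adj.items()}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    # -- text serialization --------------------------------------------------

    def save(self, edge_path, label_path=None):
        np.savetxt(edge_path, self.edges, fmt="%d", delimiter="\t")
        if label_path is not None:
            names = (
                [self.label_names[c] for c in self.y]
                if self.label_names is not None
                else list(self.y)
            )
            pd.DataFrame(
                {"cell_id": np.arange(self.n_nodes), "cell_type": names}
            ).to_csv(label_path, index=False)


def edge_homophily(edges: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of undirected edges whose endpoints share a label.

    Each undirected edge is counted once; raises on an empty edge set.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.shape[0] == 0:
        raise ValueError("edge homophily is undefined for an empty edge set")
    labels = np.asarray(labels)
    same = labels[edges[:, 0]] == labels[edges[:, 1]]
    return float(np.mean(same))


def edges_from_dense(W: np.ndarray) -> np.ndarray:
    """Undirected edge list {i, j} (i < j) wherever W[i,j] > 0 or W[j,i] > 0."""
    A = (W > 0) | (W > 0).T
    np.fill_diagonal(A, False)
    iu, ju = np.where(np.triu(A, k=1))
    return np.stack([iu, ju], axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# ligand-receptor scoring (vectorized pipeline)
# ---------------------------------------------------------------------------


def parse_receptor(receptor: str) -> list[str]:
    """Split a receptor complex into subunit gene names ('A_B' -> ['A', 'B'])."""
    return receptor.split("_")


def _expr_and_genes(expr) -> tuple[np.ndarray, dict[str, int]]:
    if isinstance(expr, ad.AnnData):
        X = expr.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        gene_index = {g: i for i, g in enumerate(expr.var_names)}
    else:
        raise TypeError("expr must be an AnnData of cells x genes")
    return np.asarray(X, dtype=np.float64), gene_index


def _check_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError("pair table needs 'ligand' and 'receptor' columns")
    if pairs.duplicated(["ligand", "receptor"]).any():
        pairs = pairs.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)
    return pairs


def binarize_ligands(expr: ad.AnnData, pairs: pd.DataFrame, T: float = 0.0) -> np.ndarray:
    """Pairs x cells {0,1} matrix: ligand of pair i detected above T in each cell.

    A ligand gene absent from the expression matrix yields an all-zero row.
    """
    X, gene_index = _expr_and_genes(expr)
    pairs = _check_pairs(pairs)
    L = np.zeros((len(pairs), X.shape[0]), dtype=np.uint8)
    for i, lig in enumerate(pairs["ligand"]):
        j = gene_index.get(lig)
        if j is not None:
            L[i] = X[:, j] > T
    return L


def binarize_receptors(expr: ad.AnnData, pairs: pd.DataFrame, T: float = 0.0) -> np.ndarray:
    """Pairs x cells {0,1} matrix: ALL receptor subunits above T in each cell.

    A receptor with any subunit absent from the gene list yields a zero row.
    """
    X, gene_index = _expr_and_genes(expr)
    pairs = _check_pairs(pairs)
    R = np.zeros((len(pairs), X.shape[0]), dtype=np.uint8)
    for i, rec in enumerate(pairs["receptor"]):
        subunits = parse_receptor(rec)
        cols = [gene_index.get(s) for s in subunits]
        if any(c is None for c in cols):
            continue
        ind = np.ones(X.shape[0], dtype=bool)
        for c in cols:
            ind &= X[:, c] > T
        R[i] = ind
    return R


def score_interactions(L: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Raw sender x receiver interaction scores W[s, j] = sum_i L[i, s] * R[i, j]."""
    L = np.asarray(L)
    R = np.asarray(R)
    if L.shape != R.shape:
        raise ValueError(
            f"ligand and receptor indicators must share shape, got {L.shape} vs {R.shape}"
        )
    return (L.astype(np.float64).T @ R.astype(np.float64))


def normalize_and_threshold(W: np.ndarray, keep_fraction: float = 0.10) -> np.ndarray:
    """Scale W by its global max and keep the top `keep_fraction` of nonzero weights.

    The cut value is the weight ranked ceil(keep_fraction * k) from the top
    among the k nonzero entries; ties at the boundary are kept, so the result
    is independent of sort order. keep_fraction must lie in (0, 1].
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    W = np.asarray(W, dtype=np.float64).copy()
    wmax = W.max() if W.size else 0.0
    if wmax <= 0:
        warnings.warn("all-zero interaction matrix; normalization skipped")
        return W
    W /= wmax
    nz = W[W > 0]
    n_keep = int(np.ceil(keep_fraction * nz.size))
    cutoff = np.sort(nz)[::-1][n_keep - 1]
    W[W < cutoff] = 0.0
    return W


def ensure_connectivity(W_raw: np.ndarray, W_thresh: np.ndarray) -> np.ndarray:
    """Reconnect cells isolated by thresholding using pre-threshold scores.

    A cell is isolated when its off-diagonal row AND column in `W_thresh` are
    all zero. Cells are scanned in index order and an earlier repair can
    un-isolate a later cell, so each added edge is conditional on the current
    state. An isolated cell is linked to its strongest raw partner (argmax of
    its raw row, excluding itself); if its raw row carries no signal at all,
    to the cell with the largest total raw weight. The repaired entry gets
    the minimum surviving positive weight so it cannot outrank real signal.
    """
    W_raw = np.asarray(W_raw, dtype=np.float64)
    W = np.asarray(W_thresh, dtype=np.float64).copy()
    n = W.shape[0]
    if n < 2:
        warnings.warn("single-cell matrix; connectivity repair is a no-op")
        return W

    off = W.copy()
    np.fill_diagonal(off, 0.0)
    pos = W[(~np.eye(n, dtype=bool)) & (W > 0)]
    fill = pos.min() if pos.size else 1.0
    strength = W_raw.sum(axis=0) + W_raw.sum(axis=1) - 2 * np.diag(W_raw)

    row_nz = (off > 0).sum(axis=1)
    col_nz = (off > 0).sum(axis=0)
    for i in range(n):
        if row_nz[i] or col_nz[i]:
            continue
        row = W_raw[i].copy()
        row[i] = -np.inf
        if np.max(row) > 0:
            j = int(np.argmax(row))
        else:
            s = strength.copy()
            s[i] = -np.inf
            j = int(np.argmax(s))
        W[i, j] = fill
        row_nz[i] += 1
        col_nz[j] += 1
    return W


def build_ccc_graph(
    expr: ad.AnnData,
    pairs: pd.DataFrame,
    labels=None,
    features: np.ndarray | None = None,
    T: float = 0.0,
    keep_fraction: float = 0.10,
) -> CellGraph:
    """Full communication-graph construction on a log-normalized expression matrix.

    Composes binarize -> score -> normalize/threshold -> connectivity repair,
    excludes self-communication, and symmetrizes by union: the undirected edge
    {i, j} exists whenever either directed score survives. Cell-type labels
    come from `labels` or from ``expr.obs['cell_type']``; node features default
    to the expression matrix itself.
    """
    if labels is None:
        if "cell_type" not in expr.obs:
            raise ValueError("labels not given and obs['cell_type'] missing")
        labels = expr.obs["cell_type"]
    labels = pd.Categorical(np.asarray(labels))
    y = labels.codes.astype(np.int64)

    L = binarize_ligands(expr, pairs, T)
    R = binarize_receptors(expr, pairs, T)
    W = score_interactions(L, R)
    np.fill_diagonal(W, 0.0)
    W_thr = normalize_and_threshold(W, keep_fraction)
    W_fix = ensure_connectivity(W, W_thr)
    edges = edges_from_dense(W_fix)

    if features is None:
        X = expr.X
        features = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    graph = CellGraph(
        n_nodes=expr.n_obs,
        edges=edges,
        y=y,
        X=np.asarray(features, dtype=np.float64),
        label_names=list(labels.categories),
    )
    graph._h = edge_homophily(graph.edges, graph.y) if graph.n_edges else None
    return graph


# ---------------------------------------------------------------------------
# Planetoid bundle
# ---------------------------------------------------------------------------


@dataclass
class PlanetoidBundle:
    """The eight-field semi-supervised node-classification layout.

    Nodes are re-indexed so rows of `allx` are nodes 0..len(allx)-1 (training
    nodes first, then unlabeled nodes) and test nodes take the remaining
    indices, listed in `test_index`. `graph` is a symmetric adjacency
    dictionary over the re-indexed nodes.
    """

    x: np.ndarray
    y: np.ndarray
    allx: np.ndarray
    ally: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    graph: dict[int, list[int]]
    test_index: np.ndarray
    label_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.allx.shape[0] + self.tx.shape[0]

    def to_arrays(self):
        """Reassemble (features, int labels, edge list, train idx, test idx)."""
        n = self.n_nodes
        feats = np.zeros((n, self.allx.shape[1]))
        labels = np.zeros(n, dtype=np.int64)
        all_idx = np.setdiff1d(np.arange(n), self.test_index)
        feats[all_idx] = self.allx
        labels[all_idx] = np.argmax(self.ally, axis=1)
        feats[self.test_index] = self.tx
        labels[self.test_index] = np.argmax(self.ty, axis=1)
        seen = set()
        edges = []
        for u, nbrs in self.graph.items():
            for v in nbrs:
                key = (min(u, v), max(u, v))
                if u != v and key not in seen:
                    seen.add(key)
                    edges.append(key)
        edges = np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)
        train_idx = np.arange(self.x.shape[0])
        return feats, labels, edges, train_idx, np.asarray(self.test_index)

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("x", "y", "allx", "ally", "tx", "ty"):
            np.savetxt(outdir / f"{name}.tsv", getattr(self, name), delimiter="\t")
        with open(outdir / "graph.json", "w") as fh:
            json.dump({str(k): v for k, v in self.graph.items()}, fh)
        np.savetxt(outdir / "test.index", self.test_index, fmt="%d")
        meta = {"label_names": self.label_names}
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, indir):
        indir = Path(indir)
        arrs = {
            name: np.loadtxt(indir / f"{name}.tsv", delimiter="\t", ndmin=2)
            for name in ("x", "y", "allx", "ally", "tx", "ty")
        }
        with open(indir / "graph.json") as fh:
            graph = {int(k): list(map(int, v)) for k, v in json.load(fh).items()}
        test_index = np.loadtxt(indir / "test.index", dtype=np.int64, ndmin=1)
        with open(indir / "meta.json") as fh:
            meta = json.load(fh)
        return cls(
            arrs["x"], arrs["y"], arrs["allx"], arrs["ally"], arrs["tx"], arrs["ty"],
            graph, test_index, meta.get("label_names"),
        )


def to_planetoid(graph: CellGraph, split) -> PlanetoidBundle:
    """Convert a cell graph plus a train/test split into a Planetoid bundle."""
    train = np.asarray(split.train_indices, dtype=np.int64)
    test = np.asarray(split.test_indices, dtype=np.int64)
    if np.intersect1d(train, test).size:
        raise ValueError("train and test indices overlap")
    n = graph.n_nodes
    if graph.X is None:
        raise ValueError("graph has no node features")
    rest = np.setdiff1d(np.arange(n), np.concatenate([train, test]))
    perm = np.concatenate([train, rest, test])  # old index per new position
    new_of_old = np.empty(n, dtype=np.int64)
    new_of_old[perm] = np.arange(n)

    k = int(graph.y.max()) + 1
    onehot = np.eye(k)[graph.y]
    X = graph.X

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for u, v in graph.edges:
        nu, nv = int(new_of_old[u]), int(new_of_old[v])
        adj[nu].append(nv)
        adj[nv].append(nu)
    adj = {i: sorted(v) for i, v in adj.items()}

    n_all = len(train) + len(rest)
    return PlanetoidBundle(
        x=X[train],
        y=onehot[train],
        allx=X[np.concatenate([train, rest])],
        ally=onehot[np.concatenate([train, rest])],
        tx=X[test],
        ty=onehot[test],
        graph=adj,
        test_index=np.arange(n_all, n, dtype=np.int64),
        label_names=graph.label_names,
    )
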