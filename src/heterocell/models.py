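"""Node classifiers for cell-type prediction on cell graphs.

Seven models share one interface: an MLP baseline that ignores the graph,
four homophily-assuming GNNs (GCN with symmetric-normalized propagation,
GraphSAGE with mean aggregation and ego concatenation, GAT with additive
attention, MixHop with concatenated powers of the normalized adjacency), and
two heterophily-aware designs:

* H2GCN keeps ego and neighbor embeddings separate, aggregates 1-hop and
  exactly-2-hop neighborhoods by degree-normalized means, and classifies the
  concatenation of every round's representation.
* GBK-GNN transforms each neighbor through two kernels — W_s for homophilic
  and W_d for heterophilic pairs — mixed by a learned sigmoid gate, with the
  gate supervised on training-edge label agreement.

All parameters are seeded uniform fan-in; training is full-batch Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .autodiff import (
    Adam,
    Tensor,
    bce_with_logits,
    concat,
    gather,
    parameter,
    segment_sum,
    softmax_cross_entropy,
    spmm,
    uniform_fan_in,
)

__all__ = [
    "MODEL_NAMES",
    "ModelConfig",
    "GraphOperators",
    "GateSignals",
    "build_model",
    "baseline_forward",
    "h2gcn_round",
    "h2gcn_final",
    "h2gcn_classify",
    "gbk_layer",
    "gbk_loss",
    "softmax",
]

MODEL_NAMES = ("MLP", "GCN", "GraphSAGE", "GAT", "MixHop", "H2GCN", "GBKGNN")


@dataclass
class ModelConfig:
    """Hyperparameters; `for_model` applies the per-architecture defaults
    (GBK-GNN trains at 0.001, MixHop uses the higher 0.7 dropout)."""

    model_name: str = "GCN"
    hidden_dim: int = 64
    n_layers: int = 2
    dropout: float = 0.5
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 300
    heads: int = 8
    powers: tuple = (0, 1, 2)
    hops: int = 2
    lam: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}; choose from {MODEL_NAMES}")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must lie in [0, 1]")
        if self.hidden_dim <= 0 or self.epochs <= 0:
            raise ValueError("hidden_dim and epochs must be positive")

    @classmethod
    def for_model(cls, name: str, **overrides) -> "ModelConfig":
        cfg = cls(model_name=name)
        if name == "GBKGNN":
            cfg = replace(cfg, learning_rate=0.001, epochs=400)
        if name == "MixHop":
            cfg = replace(cfg, dropout=0.7)
        return replace(cfg, **overrides)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# graph operators
# ---------------------------------------------------------------------------


def _row_normalize(A: sp.spmatrix) -> sp.csr_matrix:
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    return sp.diags(inv) @ A.tocsr()


@dataclass
class GraphOperators:
    """Precomputed propagation matrices and edge arrays for one graph."""

    n: int
    edges: np.ndarray  # undirected (m, 2)
    src: np.ndarray  # directed, both orientations
    dst: np.ndarray
    A: sp.csr_matrix  # symmetric adjacency, no self-loops
    gcn_norm: sp.csr_matrix  # D~^-1/2 (A + I) D~^-1/2
    row_norm: sp.csr_matrix  # D^-1 A (neighbor mean)
    hop_means: list  # row-mean operators over N_1, N_2 (exact distance)
    deg: np.ndarray

    @classmethod
    def from_edges(cls, n: int, edges: np.ndarray, hops: int = 2) -> "GraphOperators":
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            src = np.concatenate([edges[:, 0], edges[:, 1]])
            dst = np.concatenate([edges[:, 1], edges[:, 0]])
        else:
            src = dst = np.zeros(0, dtype=np.int64)
        A = sp.coo_matrix(
            (np.ones(src.size), (dst, src)), shape=(n, n)
        ).tocsr()
        A.data[:] = 1.0
        At = A + sp.eye(n, format="csr")
        deg_t = np.asarray(At.sum(axis=1)).ravel()
        dinv = sp.diags(1.0 / np.sqrt(deg_t))
        gcn_norm = (dinv @ At @ dinv).tocsr()

        hop_bools = _exact_hop_sets(A, hops)
        hop_means = [_row_normalize(h.astype(np.float64)) for h in hop_bools]
        deg = np.asarray(A.sum(axis=1)).ravel()
        return cls(n, edges, src, dst, A, gcn_norm, _row_normalize(A), hop_means, deg)

    @classmethod
    def from_graph(cls, graph, hops: int = 2) -> "GraphOperators":
        return cls.from_edges(graph.n_nodes, graph.edges, hops)


def _exact_hop_sets(A: sp.csr_matrix, hops: int) -> list[sp.csr_matrix]:
    """Boolean matrices H_k with H_k[v, u] = 1 iff dist(v, u) == k, k = 1..hops."""
    n = A.shape[0]
    B = (A > 0).astype(np.int8)
    sets = [B.copy()]
    closer = sp.eye(n, dtype=np.int8, format="csr") + B  # dist <= 1
    power = B
    for _ in range(1, hops):
        power = ((power @ B) > 0).astype(np.int8)
        exact = power - power.multiply(closer > 0)
        exact.eliminate_zeros()
        sets.append(exact)
        closer = ((closer + power) > 0).astype(np.int8)
    return [s.astype(bool).astype(np.int8).tocsr() for s in sets]


def _dropout(t: Tensor, rate: float, rng, training: bool) -> Tensor:
    if not training or rate <= 0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * mask


def _segment_softmax(e: Tensor, seg: np.ndarray, n: int) -> Tensor:
    m = np.full((n, 1), -np.inf)
    np.maximum.at(m, seg, e.data)
    m[~np.isfinite(m)] = 0.0
    w = (e - Tensor(m[seg, 0].reshape(-1, 1))).exp()
    denom = segment_sum(w, seg, n)
    return w / gather(denom, seg)


# ---------------------------------------------------------------------------
# shared parameter helpers
# ---------------------------------------------------------------------------


class _Base:
    name: str

    def __init__(self):
        self.params: list[Tensor] = []

    def _linear(self, rng, fan_in, fan_out, bias=True):
        W = parameter(uniform_fan_in(rng, fan_in, (fan_in, fan_out)))
        self.params.append(W)
        if bias:
            b = parameter(uniform_fan_in(rng, fan_in, (fan_out,)))
            self.params.append(b)
            return W, b
        return W, None

    def loss(self, logits: Tensor, labels, train_idx) -> Tensor:
        return softmax_cross_entropy(gather(logits, train_idx), np.asarray(labels)[train_idx])


class MLP(_Base):
    """Two-layer perceptron on node features; the graph is ignored."""

    name = "MLP"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg = cfg
        self.W1, self.b1 = self._linear(rng, in_dim, cfg.hidden_dim)
        self.W2, self.b2 = self._linear(rng, cfg.hidden_dim, n_classes)

    def forward(self, X: Tensor, rng=None, training=False) -> Tensor:
        h = _dropout(X, self.cfg.dropout, rng, training)
        h = (h @ self.W1 + self.b1).relu()
        h = _dropout(h, self.cfg.dropout, rng, training)
        return h @ self.W2 + self.b2


class GCN(_Base):
    """Symmetric-normalized propagation with self-loops, two layers."""

    name = "GCN"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        self.W1, self.b1 = self._linear(rng, in_dim, cfg.hidden_dim)
        self.W2, self.b2 = self._linear(rng, cfg.hidden_dim, n_classes)

    def forward(self, X, rng=None, training=False):
        h = _dropout(X, self.cfg.dropout, rng, training)
        h = (spmm(self.ops.gcn_norm, h @ self.W1) + self.b1).relu()
        h = _dropout(h, self.cfg.dropout, rng, training)
        return spmm(self.ops.gcn_norm, h @ self.W2) + self.b2


class GraphSAGE(_Base):
    """Mean neighbor aggregation concatenated with the ego embedding."""

    name = "GraphSAGE"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        self.W1, self.b1 = self._linear(rng, 2 * in_dim, cfg.hidden_dim)
        self.W2, self.b2 = self._linear(rng, 2 * cfg.hidden_dim, n_classes)

    def _layer(self, h, W, b):
        return concat([h, spmm(self.ops.row_norm, h)], axis=1) @ W + b

    def forward(self, X, rng=None, training=False):
        h = _dropout(X, self.cfg.dropout, rng, training)
        h = self._layer(h, self.W1, self.b1).relu()
        h = _dropout(h, self.cfg.dropout, rng, training)
        return self._layer(h, self.W2, self.b2)


class GAT(_Base):
    """Additive attention over neighbors (with self-loops), multi-head hidden
    layer with concatenation, single-head output layer."""

    name = "GAT"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        self.heads = cfg.heads
        f = max(cfg.hidden_dim // cfg.heads, 1)
        self.f = f
        self.Wh, self.al, self.ar = [], [], []
        for _ in range(cfg.heads):
            W, _ = self._linear(rng, in_dim, f, bias=False)
            a_l = parameter(uniform_fan_in(rng, f, (f, 1)))
            a_r = parameter(uniform_fan_in(rng, f, (f, 1)))
            self.params += [a_l, a_r]
            self.Wh.append(W)
            self.al.append(a_l)
            self.ar.append(a_r)
        self.Wo, _ = self._linear(rng, cfg.heads * f, n_classes, bias=False)
        self.ao_l = parameter(uniform_fan_in(rng, n_classes, (n_classes, 1)))
        self.ao_r = parameter(uniform_fan_in(rng, n_classes, (n_classes, 1)))
        self.params += [self.ao_l, self.ao_r]
        # attention edges include self-loops
        loops = np.arange(ops.n, dtype=np.int64)
        self.asrc = np.concatenate([ops.src, loops])
        self.adst = np.concatenate([ops.dst, loops])

    def _attend(self, h, W, a_l, a_r):
        Wh = h @ W
        e = gather(Wh @ a_l, self.adst) + gather(Wh @ a_r, self.asrc)
        alpha = _segment_softmax(e.leaky_relu(0.2), self.adst, self.ops.n)
        return segment_sum(alpha * gather(Wh, self.asrc), self.adst, self.ops.n)

    def forward(self, X, rng=None, training=False):
        h = _dropout(X, self.cfg.dropout, rng, training)
        heads = [
            self._attend(h, W, al, ar).relu()
            for W, al, ar in zip(self.Wh, self.al, self.ar)
        ]
        h = _dropout(concat(heads, axis=1), self.cfg.dropout, rng, training)
        return self._attend(h, self.Wo, self.ao_l, self.ao_r)


class MixHop(_Base):
    """Concatenated powers of the normalized adjacency per layer."""

    name = "MixHop"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        self.powers = tuple(cfg.powers)
        self.L1 = [self._linear(rng, in_dim, cfg.hidden_dim) for _ in self.powers]
        width = cfg.hidden_dim * len(self.powers)
        self.L2 = [self._linear(rng, width, cfg.hidden_dim) for _ in self.powers]
        self.Wo, self.bo = self._linear(rng, width, n_classes)

    def _mix(self, h, layers):
        outs = []
        for p, (W, b) in zip(self.powers, layers):
            z = h @ W + b
            for _ in range(p):
                z = spmm(self.ops.gcn_norm, z)
            outs.append(z)
        return concat(outs, axis=1)

    def forward(self, X, rng=None, training=False):
        h = _dropout(X, self.cfg.dropout, rng, training)
        h = self._mix(h, self.L1).relu()
        h = _dropout(h, self.cfg.dropout, rng, training)
        h = self._mix(h, self.L2).relu()
        h = _dropout(h, self.cfg.dropout, rng, training)
        return h @ self.Wo + self.bo


# ---------------------------------------------------------------------------
# H2GCN
# ---------------------------------------------------------------------------


def h2gcn_round(embeddings, hop_means) -> Tensor:
    """One aggregation round: concatenate degree-normalized means over each
    exact-distance hop set. The ego embedding is NOT mixed in; a node with an
    empty hop set contributes a zero vector for that term."""
    t = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    return concat([spmm(H, t) for H in hop_means], axis=1)


def h2gcn_final(all_round_embeddings) -> Tensor:
    """Concatenate the initial projection and every round's output."""
    ts = [e if isinstance(e, Tensor) else Tensor(e) for e in all_round_embeddings]
    return concat(ts, axis=1)


def h2gcn_classify(final, Wc) -> np.ndarray:
    """Row-stochastic class probabilities softmax(r_final W_c)."""
    t = final.data if isinstance(final, Tensor) else np.asarray(final)
    W = Wc.data if isinstance(Wc, Tensor) else np.asarray(Wc)
    if t.shape[1] != W.shape[0]:
        raise ValueError(f"dimension mismatch: {t.shape[1]} vs {W.shape[0]}")
    return softmax(t @ W)


class H2GCN(_Base):
    """Ego/neighbor separation, exact 1- and 2-hop means, concatenation of
    all rounds into the classifier."""

    name = "H2GCN"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        self.K = cfg.n_layers
        self.We, self.be = self._linear(rng, in_dim, cfg.hidden_dim)
        n_hops = len(ops.hop_means)
        final_dim = cfg.hidden_dim * sum(n_hops**k for k in range(self.K + 1))
        self.Wc, _ = self._linear(rng, final_dim, n_classes, bias=False)

    def forward(self, X, rng=None, training=False):
        h = _dropout(X, self.cfg.dropout, rng, training)
        r = (h @ self.We + self.be).relu()
        rounds = [r]
        for _ in range(self.K):
            rounds.append(h2gcn_round(rounds[-1], self.ops.hop_means))
        final = _dropout(h2gcn_final(rounds), self.cfg.dropout, rng, training)
        return final @ self.Wc


# ---------------------------------------------------------------------------
# GBK-GNN
# ---------------------------------------------------------------------------


@dataclass
class GateSignals:
    """Per-directed-edge gate activations of one GBK layer."""

    alpha: Tensor  # sigmoid outputs, (E, 1)
    logits: Tensor  # pre-sigmoid gate values, (E, 1)
    src: np.ndarray
    dst: np.ndarray


def gbk_layer(
    embeddings,
    ops: GraphOperators,
    kernels,
    gate,
    activation: str = "relu",
) -> tuple[Tensor, GateSignals]:
    """One bi-kernel gated layer.

    z'_i = sigma( W_f z_i + (1/|N(i)|) sum_j [ a_ij W_s z_j + (1 - a_ij) W_d z_j ] )

    `kernels` is (W_f, b_f, W_s, W_d); `gate` is the two-layer perceptron
    (Wg1, bg1, Wg2, bg2) applied to the concatenation [z_i, z_j]. Isolated
    nodes receive a zero neighbor term.
    """
    z = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    Wf, bf, Ws, Wd = kernels
    Wg1, bg1, Wg2, bg2 = gate
    src, dst = ops.src, ops.dst
    n = ops.n

    zi = gather(z, dst)
    zj = gather(z, src)
    g_logits = (concat([zi, zj], axis=1) @ Wg1 + bg1).relu() @ Wg2 + bg2
    alpha = g_logits.sigmoid()
    msg = alpha * (zj @ Ws) + (1.0 - alpha) * (zj @ Wd)
    agg = segment_sum(msg, dst, n) * (1.0 / np.maximum(ops.deg, 1.0))[:, None]
    out = z @ Wf + bf + agg
    if activation == "relu":
        out = out.relu()
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    return out, GateSignals(alpha=alpha, logits=g_logits, src=src, dst=dst)


def gbk_loss(
    class_scores: Tensor,
    labels: np.ndarray,
    gates: list[GateSignals],
    lam: float,
    train_mask: np.ndarray,
) -> Tensor:
    """L = L_o + lambda * sum_l L_g^l.

    L_o is cross-entropy on training nodes; each L_g^l is binary
    cross-entropy of the layer's gate against the same-label indicator,
    evaluated only on edges with BOTH endpoints in the training set (no
    label leakage through the gate).
    """
    labels = np.asarray(labels)
    train_mask = np.asarray(train_mask, dtype=bool)
    train_idx = np.where(train_mask)[0]
    total = softmax_cross_entropy(gather(class_scores, train_idx), labels[train_idx])
    if lam == 0:
        return total
    for gs in gates:
        eligible = train_mask[gs.src] & train_mask[gs.dst]
        if not eligible.any():
            warnings.warn("no train-train edges; gate supervision term is 0")
            continue
        idx = np.where(eligible)[0]
        target = (labels[gs.src[idx]] == labels[gs.dst[idx]]).astype(np.float64)
        total = total + lam * bce_with_logits(gather(gs.logits, idx), target.reshape(-1, 1))
    return total


class GBKGNN(_Base):
    """Two gated bi-kernel layers; ReLU between, identity before softmax."""

    name = "GBKGNN"

    def __init__(self, cfg, in_dim, n_classes, ops, rng):
        super().__init__()
        self.cfg, self.ops = cfg, ops
        gate_hidden = 16
        self.layers = []
        dims = [in_dim, cfg.hidden_dim, n_classes]
        for l in range(2):
            d_in, d_out = dims[l], dims[l + 1]
            Wf, bf = self._linear(rng, d_in, d_out)
            Ws, _ = self._linear(rng, d_in, d_out, bias=False)
            Wd, _ = self._linear(rng, d_in, d_out, bias=False)
            Wg1, bg1 = self._linear(rng, 2 * d_in, gate_hidden)
            Wg2, bg2 = self._linear(rng, gate_hidden, 1)
            self.layers.append(
                {"kernels": (Wf, bf, Ws, Wd), "gate": (Wg1, bg1, Wg2, bg2)}
            )

    def forward(self, X, rng=None, training=False, return_gates=False):
        gates = []
        h = _dropout(X, self.cfg.dropout, rng, training)
        h, g1 = gbk_layer(h, self.ops, **self.layers[0], activation="relu")
        gates.append(g1)
        h = _dropout(h, self.cfg.dropout, rng, training)
        h, g2 = gbk_layer(h, self.ops, **self.layers[1], activation="identity")
        gates.append(g2)
        if return_gates:
            return h, gates
        return h

    def loss(self, logits_and_gates, labels, train_idx) -> Tensor:
        logits, gates = logits_and_gates
        n = logits.data.shape[0]
        mask = np.zeros(n, dtype=bool)
        mask[np.asarray(train_idx)] = True
        return gbk_loss(logits, labels, gates, self.cfg.lam, mask)


_MODEL_CLASSES = {
    "MLP": MLP,
    "GCN": GCN,
    "GraphSAGE": GraphSAGE,
    "GAT": GAT,
    "MixHop": MixHop,
    "H2GCN": H2GCN,
    "GBKGNN": GBKGNN,
}


def build_model(cfg: ModelConfig, in_dim: int, n_classes: int, ops: GraphOperators):
    """Instantiate a seeded model; parameters depend only on dims and seed."""
    rng = np.random.default_rng(cfg.seed)
    cls = _MODEL_CLASSES.get(cfg.model_name)
    if cls is None:
        raise ValueError(f"unknown model {cfg.model_name!r}")
    return cls(cfg, in_dim, n_classes, ops, rng)


def baseline_forward(
    model_name: str,
    features: np.ndarray,
    graph,
    config: ModelConfig | None = None,
    n_classes: int | None = None,
) -> np.ndarray:
    """Deterministic forward pass of a freshly seeded baseline model.

    `graph` is a CellGraph or GraphOperators; returns raw class scores.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    cfg = config or ModelConfig.for_model(model_name)
    cfg = replace(cfg, model_name=model_name)
    ops = graph if isinstance(graph, GraphOperators) else GraphOperators.from_graph(graph, cfg.hops)
    X = np.asarray(features, dtype=np.float64)
    if n_classes is None:
        y = getattr(graph, "y", None)
        n_classes = int(np.max(y)) + 1 if y is not None else 2
    model = build_model(cfg, X.shape[1], n_classes, ops)
    out = model.forward(Tensor(X), training=False)
    if isinstance(out, tuple):
        out = out[0]
    return out.data
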