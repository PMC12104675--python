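"""Explicit-loop reference implementation of the communication-graph
construction, used as an independent oracle. No matrix algebra, no numpy
inside the core loops."""

import math


def naive_pipeline(gene_names, expr_rows, pairs, T, keep_fraction):
    """gene_names: list of gene identifiers; expr_rows: list (per cell) of
    lists of expression values; pairs: list of (ligand, receptor) with
    '_'-joined receptor subunits. Returns (W_raw, W_final, edge_set) as
    nested lists / set of (i, j) with i < j."""
    gidx = {g: k for k, g in enumerate(gene_names)}
    n = len(expr_rows)
    L = [[0] * n for _ in pairs]
    R = [[0] * n for _ in pairs]
    for i, (lig, rec) in enumerate(pairs):
        if lig in gidx:
            for c in range(n):
                L[i][c] = 1 if expr_rows[c][gidx[lig]] > T else 0
        subunits = rec.split("_")
        if all(s in gidx for s in subunits):
            for c in range(n):
                R[i][c] = (
                    1
                    if all(expr_rows[c][gidx[s]] > T for s in subunits)
                    else 0
                )
    W = [[0.0] * n for _ in range(n)]
    for s in range(n):
        for j in range(n):
            acc = 0.0
            for i in range(len(pairs)):
                acc += L[i][s] * R[i][j]
            W[s][j] = acc
    for s in range(n):
        W[s][s] = 0.0  # self-communication excluded
    W_raw = [row[:] for row in W]

    wmax = max(max(row) for row in W)
    if wmax > 0:
        for s in range(n):
            for j in range(n):
                W[s][j] /= wmax
        nonzero = sorted(
            (W[s][j] for s in range(n) for j in range(n) if W[s][j] > 0),
            reverse=True,
        )
        n_keep = math.ceil(keep_fraction * len(nonzero))
        cutoff = nonzero[n_keep - 1]
        for s in range(n):
            for j in range(n):
                if W[s][j] < cutoff:
                    W[s][j] = 0.0

    survivors = [
        W[s][j] for s in range(n) for j in range(n) if s != j and W[s][j] > 0
    ]
    fill = min(survivors) if survivors else 1.0
    strength = [
        sum(W_raw[s][j] for s in range(n) if s != j)
        + sum(W_raw[j][s] for s in range(n) if s != j)
        for j in range(n)
    ]
    for i in range(n):
        row_zero = all(W[i][j] == 0 for j in range(n) if j != i)
        col_zero = all(W[j][i] == 0 for j in range(n) if j != i)
        if row_zero and col_zero and n > 1:
            best, best_w = None, 0.0
            for j in range(n):
                if j != i and W_raw[i][j] > best_w:
                    best, best_w = j, W_raw[i][j]
            if best is None:
                best = max(
                    (j for j in range(n) if j != i), key=lambda j: strength[j]
                )
            W[i][best] = fill

    edges = set()
    for s in range(n):
        for j in range(s + 1, n):
            if W[s][j] > 0 or W[j][s] > 0:
                edges.add((s, j))
    return W_raw, W, edges


def naive_edge_homophily(edges, labels):
    same = 0
    for u, v in edges:
        if labels[u] == labels[v]:
            same += 1
    return same / len(edges)


def random_instance(rng, n_cells, n_pairs, n_genes=12):
    """A random expression table and pair list, including missing genes and
    multi-subunit receptors."""
    gene_names = [f"g{k}" for k in range(n_genes)]
    expr = (
        rng.random((n_cells, n_genes)) * (rng.random((n_cells, n_genes)) < 0.5)
    ).tolist()
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        lig = gene_names[rng.integers(0, n_genes)]
        if rng.random() < 0.3:
            rec = "_".join(sorted(rng.choice(gene_names, size=2, replace=False)))
        else:
            rec = gene_names[rng.integers(0, n_genes)]
        if rng.random() < 0.1:
            rec = "missing0" if rng.random() < 0.5 else rec + "_missingX"
        if rng.random() < 0.1:
            lig = "missing1"
        if (lig, rec) not in seen:
            seen.add((lig, rec))
            pairs.append((lig, rec))
    return gene_names, expr, pairs
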