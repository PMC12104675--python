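"""Synthetic droplet scRNA-seq datasets and homophily-controlled cell graphs.

The generator emulates the statistical shape of droplet-based pancreatic
islet data: ~14 cell types with skewed abundances, gamma-Poisson (negative
binomial) UMI counts with log-normal gene means, a marker-gene block per
type, a small high-expression mitochondrial gene set (names prefixed
``MT-``) for QC, and implanted ligand-receptor expression programs that let
the communication-graph construction recover a designed sender->receiver
type structure. A separate generator places edges directly to hit a target
edge homophily ratio, standing in for graphs built from expression-space
neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ccc_graph import CellGraph, edge_homophily

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_labels",
    "generate_counts",
    "implant_lr_programs",
    "generate_graph_with_homophily",
    "simulate_dataset",
    "write_dataset",
    "read_counts_mtx",
]


def _default_proportions(n_types: int) -> np.ndarray:
    # geometric decay mimics the skew of islet type abundances
    p = 0.82 ** np.arange(n_types)
    return p / p.sum()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    marker_logfc is a natural-log fold change applied to each type's marker
    block; nb_dispersion is the negative-binomial dispersion phi in
    Var = mu + phi * mu^2 (phi -> 0 recovers Poisson).
    """

    n_cells: int = 1000
    n_genes: int = 2000
    n_types: int = 14
    type_proportions: np.ndarray | None = None
    library_size_mean: float = 2500.0
    library_size_cv: float = 0.3
    nb_dispersion: float = 0.3
    marker_logfc: float = 1.2
    markers_per_type: int = 10
    n_lr_pairs: int = 30
    multi_subunit_fraction: float = 0.25
    communication_design: np.ndarray | None = None
    mito_gene_fraction: float = 0.005
    mito_expr_fraction: float = 0.03
    seed: int = 0
    type_names: list[str] = field(init=False)

    def __post_init__(self):
        if min(self.n_cells, self.n_genes, self.n_types) <= 0:
            raise ValueError("counts of cells, genes and types must be positive")
        if self.type_proportions is None:
            self.type_proportions = _default_proportions(self.n_types)
        self.type_proportions = np.asarray(self.type_proportions, dtype=np.float64)
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1 within 1e-9")
        if (self.type_proportions <= 0).any():
            raise ValueError("type_proportions entries must be positive")
        if self.communication_design is None:
            self.communication_design = np.eye(self.n_types)
        self.communication_design = np.asarray(
            self.communication_design, dtype=np.float64
        )
        if self.communication_design.shape != (self.n_types, self.n_types):
            raise ValueError("communication_design must be n_types x n_types")
        self.type_names = [f"type_{k:02d}" for k in range(self.n_types)]

    def rng(self, stream: int) -> np.random.Generator:
        """Named random stream so stages draw independently but reproducibly."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class SyntheticDataset:
    counts: ad.AnnData  # cells x genes UMI counts, obs['cell_type'] set
    labels: np.ndarray  # integer type codes per cell
    lr_pairs: pd.DataFrame  # columns ligand, receptor ('_'-joined subunits)
    truth: SimulationConfig


def generate_labels(cfg: SimulationConfig) -> np.ndarray:
    """Draw each cell's type from the configured proportions."""
    rng = cfg.rng(0)
    return rng.choice(cfg.n_types, size=cfg.n_cells, p=cfg.type_proportions)


def _nb_counts(rng, mu, phi):
    """Gamma-Poisson draw with Var = mu + phi mu^2; phi ~ 0 is Poisson."""
    if phi < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def generate_counts(labels: np.ndarray, cfg: SimulationConfig) -> ad.AnnData:
    """Negative-binomial count matrix with type markers and mitochondrial genes.

    Gene base means are log-normal; each type owns a marker block whose mean
    is multiplied by exp(marker_logfc) in cells of that type. A small gene set
    is renamed with the 'MT-' prefix and given elevated expression so the
    mitochondrial QC filter has something to act on.
    """
    labels = np.asarray(labels)
    rng = cfg.rng(1)
    n, g = cfg.n_cells, cfg.n_genes

    base = np.exp(rng.normal(loc=0.0, scale=1.3, size=g))
    n_mito = max(3, int(round(cfg.mito_gene_fraction * g)))
    mito_idx = np.arange(g - n_mito, g)
    # scale mitochondrial means so their expected share of the library equals
    # mito_expr_fraction; NB noise then puts a realistic tail past QC cutoffs
    other_sum = base[:-n_mito].sum()
    target = cfg.mito_expr_fraction / (1.0 - cfg.mito_expr_fraction) * other_sum
    base[mito_idx] *= target / base[mito_idx].sum()

    # per-type mean profiles: marker block up-regulated
    profiles = np.tile(base, (cfg.n_types, 1))
    marker_genes = {}
    for t in range(cfg.n_types):
        lo = t * cfg.markers_per_type
        hi = lo + cfg.markers_per_type
        if hi > g - n_mito:
            break
        marker_genes[t] = np.arange(lo, hi)
        profiles[t, lo:hi] *= np.exp(cfg.marker_logfc)
    profiles /= profiles.sum(axis=1, keepdims=True)

    cv = cfg.library_size_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        lib = rng.lognormal(
            mean=np.log(cfg.library_size_mean) - 0.5 * sigma**2, sigma=sigma, size=n
        )
    else:
        lib = np.full(n, cfg.library_size_mean)
    mu = lib[:, None] * profiles[labels]
    counts = _nb_counts(rng, mu, cfg.nb_dispersion).astype(np.int64)

    gene_ids = [f"G{i:05d}" for i in range(g)]
    for k, i in enumerate(mito_idx):
        gene_ids[i] = f"MT-G{k:02d}"
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {
                "cell_type": pd.Categorical(
                    [cfg.type_names[t] for t in labels], categories=cfg.type_names
                )
            },
            index=[f"cell_{i:05d}" for i in range(n)],
        ),
        var=pd.DataFrame(index=gene_ids),
    )
    adata.uns["marker_genes"] = {str(t): v for t, v in marker_genes.items()}
    return adata


def implant_lr_programs(
    counts: ad.AnnData, labels: np.ndarray, cfg: SimulationConfig
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Write ligand-receptor expression programs into the count matrix.

    Active entries of ``communication_design`` (sender type -> receiver type)
    are assigned ligand-receptor pairs round-robin. The ligand gene is
    expressed almost exclusively in sender-type cells and the receptor
    subunit gene(s) in receiver-type cells, so binarizing at the detection
    threshold recovers the designed program. A configured fraction of
    receptors gets two subunits, encoded 'GENEA_GENEB'.
    """
    labels = np.asarray(labels)
    rng = cfg.rng(2)
    design = np.argwhere(cfg.communication_design > 0)
    if design.size == 0:
        raise ValueError("communication_design has no active sender->receiver entries")

    n_multi = int(round(cfg.multi_subunit_fraction * cfg.n_lr_pairs))
    genes_needed = 2 * cfg.n_lr_pairs + n_multi
    gene_ids = list(counts.var_names)
    reserved = cfg.n_types * cfg.markers_per_type  # keep marker block intact
    free = [
        i
        for i in range(reserved, counts.n_vars)
        if not gene_ids[i].startswith("MT-")
    ]
    if genes_needed > len(free):
        raise ValueError(
            f"n_lr_pairs={cfg.n_lr_pairs} needs {genes_needed} free genes, "
            f"only {len(free)} available"
        )

    X = counts.X.toarray() if sp.issparse(counts.X) else np.array(counts.X)
    X = X.astype(np.int64)

    on_mean, off_mean = 6.0, 0.02
    pool = iter(free)
    records = []
    for p in range(cfg.n_lr_pairs):
        s_type, r_type = design[p % len(design)]
        lig = next(pool)
        subunits = [next(pool)]
        if p < n_multi:
            subunits.append(next(pool))
        senders = labels == s_type
        receivers = labels == r_type
        for gcol, on_cells in [(lig, senders)] + [(su, receivers) for su in subunits]:
            col = _nb_counts(rng, np.full(counts.n_obs, off_mean), cfg.nb_dispersion)
            col[on_cells] = _nb_counts(
                rng, np.full(int(on_cells.sum()), on_mean), cfg.nb_dispersion
            )
            X[:, gcol] = col
        records.append(
            {
                "ligand": gene_ids[lig],
                "receptor": "_".join(gene_ids[s] for s in subunits),
                "sender_type": cfg.type_names[s_type],
                "receiver_type": cfg.type_names[r_type],
            }
        )

    out = counts.copy()
    out.X = sp.csr_matrix(X)
    lr = pd.DataFrame.from_records(records)
    return out, lr


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Labels, counts and implanted L-R programs in one call."""
    labels = generate_labels(cfg)
    counts = generate_counts(labels, cfg)
    counts, lr = implant_lr_programs(counts, labels, cfg)
    return SyntheticDataset(counts=counts, labels=labels, lr_pairs=lr, truth=cfg)


# ---------------------------------------------------------------------------
# homophily-controlled graphs
# ---------------------------------------------------------------------------


def generate_graph_with_homophily(
    labels: np.ndarray,
    target_h: float,
    avg_degree: float = 10.0,
    seed: int = 0,
    features: np.ndarray | None = None,
    cross_design: np.ndarray | None = None,
    tol: float = 0.02,
) -> CellGraph:
    """Random simple graph whose edge homophily ratio hits ``target_h``.

    A fixed fraction target_h of the edge budget is drawn as within-class
    pairs and the rest as cross-class pairs, both by rejection sampling of
    distinct unordered pairs. Isolated nodes are then wired in, preferring
    the underrepresented edge kind, and a final swap pass nudges the realized
    ratio to within ``tol`` of the target.

    ``cross_design`` (optional, classes x classes, zero diagonal) biases
    cross-class edges toward designated class pairs, so low-homophily
    neighborhoods remain informative about the node's class.
    """
    labels = np.asarray(labels)
    n = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 and target_h < 1.0:
        raise ValueError("need at least 2 classes for cross-class edges")
    if not 0.0 <= target_h <= 1.0:
        raise ValueError("target_h must lie in [0, 1]")
    if target_h == 1.0 and (counts < 2).any():
        raise ValueError(
            "target homophily 1.0 is unreachable with a singleton class"
        )

    rng = np.random.default_rng(seed)
    m = max(n // 2 + 1, int(round(n * avg_degree / 2)))
    m_within = int(round(target_h * m))
    within_capacity = int((counts * (counts - 1) // 2).sum())
    if m_within > within_capacity:
        raise ValueError("not enough same-class pairs for the requested homophily")

    members = {c: np.where(labels == c)[0] for c in classes}
    class_p = counts / counts.sum()
    if cross_design is not None:
        cd = np.asarray(cross_design, dtype=np.float64).copy()
        np.fill_diagonal(cd, 0.0)
        if cd.sum() <= 0:
            raise ValueError("cross_design must have positive off-diagonal mass")
        cd_flat = cd.ravel() / cd.sum()

    edge_set: set[tuple[int, int]] = set()

    def add_within() -> bool:
        for _ in range(200):
            c = classes[rng.choice(classes.size, p=class_p)]
            mem = members[c]
            if mem.size < 2:
                continue
            u, v = rng.choice(mem, size=2, replace=False)
            key = (min(u, v), max(u, v))
            if key not in edge_set:
                edge_set.add(key)
                return True
        return False

    def add_cross() -> bool:
        for _ in range(200):
            if cross_design is not None:
                k = rng.choice(cd_flat.size, p=cd_flat)
                ca, cb = classes[k // classes.size], classes[k % classes.size]
            else:
                ca, cb = classes[rng.choice(classes.size, size=2, replace=False, p=class_p)]
            if ca == cb:
                continue
            u = rng.choice(members[ca])
            v = rng.choice(members[cb])
            key = (min(u, v), max(u, v))
            if key not in edge_set:
                edge_set.add(key)
                return True
        return False

    for _ in range(m_within):
        if not add_within():
            raise ValueError("could not place within-class edges; graph too dense")
    for _ in range(m - m_within):
        if not add_cross():
            raise ValueError("could not place cross-class edges; graph too dense")

    # wire in isolated nodes, preferring the currently underrepresented kind
    def realized():
        e = np.array(sorted(edge_set))
        return float(np.mean(labels[e[:, 0]] == labels[e[:, 1]]))

    deg = np.zeros(n, dtype=np.int64)
    for u, v in edge_set:
        deg[u] += 1
        deg[v] += 1
    for i in np.where(deg == 0)[0]:
        want_within = realized() < target_h
        mem = members[labels[i]]
        placed = False
        if want_within and mem.size >= 2:
            choices = mem[mem != i]
            for v in rng.permutation(choices)[:50]:
                key = (min(i, v), max(i, v))
                if key not in edge_set:
                    edge_set.add(key)
                    placed = True
                    break
        if not placed:
            others = np.where(labels != labels[i])[0]
            pool = others if others.size else np.setdiff1d(np.arange(n), [i])
            for v in rng.permutation(pool)[:200]:
                key = (min(i, v), max(i, v))
                if key not in edge_set:
                    edge_set.add(key)
                    placed = True
                    break
        if not placed:
            raise ValueError(f"could not connect isolated node {i}")

    # swap pass: replace edges of the overrepresented kind (degree-safely)
    for _ in range(20 * m):
        e = np.array(sorted(edge_set))
        h = float(np.mean(labels[e[:, 0]] == labels[e[:, 1]]))
        if abs(h - target_h) <= tol:
            break
        too_high = h > target_h
        deg = np.zeros(n, dtype=np.int64)
        np.add.at(deg, e.ravel(), 1)
        same = labels[e[:, 0]] == labels[e[:, 1]]
        removable = e[same if too_high else ~same]
        ok = removable[(deg[removable[:, 0]] > 1) & (deg[removable[:, 1]] > 1)]
        if not ok.size:
            break
        u, v = ok[rng.integers(ok.shape[0])]
        edge_set.discard((min(u, v), max(u, v)))
        if not (add_cross() if too_high else add_within()):
            edge_set.add((min(u, v), max(u, v)))
            break

    edges = np.array(sorted(edge_set), dtype=np.int64)
    h = edge_homophily(edges, labels)
    if abs(h - target_h) > tol:
        raise ValueError(
            f"realized homophily {h:.3f} outside +/-{tol} of target {target_h}"
        )
    g = CellGraph(n_nodes=n, edges=edges, y=labels.astype(np.int64), X=features)
    g._h = h
    return g


def benchmark_graph(
    target_h: float,
    n_cells: int = 800,
    n_types: int = 8,
    n_features: int = 32,
    feature_scale: float = 0.5,
    avg_degree: float = 10.0,
    seed: int = 0,
) -> CellGraph:
    """Standard benchmark condition: a homophily-controlled graph over cells
    with Gaussian class-profile node features.

    Features emulate a reduced expression profile: each type has a mean
    vector drawn N(0, I), and a cell's feature is `feature_scale` times its
    type mean plus unit Gaussian noise — informative but not separable
    enough to trivialize the graph models. Cross-class edges are uniform
    over unlike pairs, so low-homophily neighborhoods carry little direct
    class signal and aggregation-only models degrade, as in heterophilic
    tissue graphs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    labels = rng.integers(0, n_types, n_cells)
    means = rng.normal(0.0, 1.0, (n_types, n_features))
    X = feature_scale * means[labels] + rng.normal(0.0, 1.0, (n_cells, n_features))
    return generate_graph_with_homophily(
        labels, target_h, avg_degree=avg_degree, seed=seed + 1, features=X
    )


# ---------------------------------------------------------------------------
# text serialization
# ---------------------------------------------------------------------------


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Matrix Market counts with TSV sidecars, labels CSV, L-R pair CSV."""
    from pathlib import Path

    import scipy.io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"), sp.coo_matrix(ds.counts.X))
    pd.Series(ds.counts.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(ds.counts.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {"cell_id": ds.counts.obs_names, "cell_type": ds.counts.obs["cell_type"]}
    ).to_csv(outdir / "labels.csv", index=False)
    ds.lr_pairs[["ligand", "receptor"]].to_csv(outdir / "lr_pairs.csv", index=False)


def read_counts_mtx(indir) -> ad.AnnData:
    """Read counts.mtx + genes.tsv + barcodes.tsv (+ labels.csv if present)."""
    from pathlib import Path

    import scipy.io

    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "counts.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    adata = ad.AnnData(
        X=X, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes)
    )
    labels_path = indir / "labels.csv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path).set_index("cell_id")
        adata.obs["cell_type"] = pd.Categorical(lab.loc[cells, "cell_type"])
    return adata
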