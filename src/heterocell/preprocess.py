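"""Quality control, normalization and feature selection for UMI count matrices.

The pipeline mirrors standard droplet scRNA-seq practice: drop cells whose
total counts exceed a doublet-suggestive ceiling or whose mitochondrial read
fraction exceeds a viability cutoff, drop genes detected in too few cells,
scale each cell to counts-per-million, apply log(1 + x) (natural log), and
keep the most highly variable genes ranked by mean-binned normalized
dispersion. Cell filters run before gene filters; gene detection is counted
on the cell-filtered matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = [
    "QCReport",
    "qc_filter_cells",
    "qc_filter_genes",
    "normalize_cpm_log",
    "select_hvg",
    "preprocess_pipeline",
]

MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_cells_out > self.n_cells_in or self.n_genes_out > self.n_genes_in:
            raise ValueError("QC cannot create cells or genes")

    @property
    def n_cells_removed(self) -> int:
        return self.n_cells_in - self.n_cells_out

    @property
    def n_genes_removed(self) -> int:
        return self.n_genes_in - self.n_genes_out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _dense(X):
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def qc_filter_cells(
    counts: ad.AnnData,
    max_total_counts: float = 14_000,
    max_mito_fraction: float = 0.05,
    mito_prefixes=MITO_PREFIXES,
) -> tuple[ad.AnnData, QCReport]:
    """Remove cells with MORE than `max_total_counts` total counts or a
    mitochondrial fraction strictly above `max_mito_fraction`.

    Both cutoffs are strict: a cell sitting exactly on a threshold survives.
    Cell order is preserved. Raises if every cell would be removed.
    """
    if counts.n_obs == 0:
        raise ValueError("empty count matrix")
    total = np.asarray(counts.X.sum(axis=1)).ravel()
    is_mito = np.array(
        [g.startswith(tuple(mito_prefixes)) for g in counts.var_names]
    )
    mito_counts = (
        np.asarray(counts[:, is_mito].X.sum(axis=1)).ravel()
        if is_mito.any()
        else np.zeros(counts.n_obs)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    keep = (total <= max_total_counts) & (mito_frac <= max_mito_fraction)
    if not keep.any():
        raise ValueError("cell QC removed every cell")
    out = counts[keep].copy()
    report = QCReport(
        n_cells_in=counts.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=counts.n_vars,
        n_genes_out=counts.n_vars,
        thresholds={
            "max_total_counts": max_total_counts,
            "max_mito_fraction": max_mito_fraction,
            "mito_prefixes": list(mito_prefixes),
        },
    )
    return out, report


def qc_filter_genes(
    counts: ad.AnnData, min_cells: int = 20
) -> tuple[ad.AnnData, QCReport]:
    """Keep genes detected (nonzero) in at least `min_cells` cells."""
    if counts.n_vars == 0:
        raise ValueError("empty count matrix")
    X = counts.X
    detected = (
        np.asarray((X > 0).sum(axis=0)).ravel()
        if sp.issparse(X)
        else (np.asarray(X) > 0).sum(axis=0)
    )
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError("gene QC removed every gene")
    out = counts[:, keep].copy()
    report = QCReport(
        n_cells_in=counts.n_obs,
        n_cells_out=counts.n_obs,
        n_genes_in=counts.n_vars,
        n_genes_out=out.n_vars,
        thresholds={"min_cells": min_cells},
    )
    return out, report


def normalize_cpm_log(counts: ad.AnnData) -> ad.AnnData:
    """log(1 + counts-per-million), natural log.

    value(c, g) = log(1 + counts(c, g) * 1e6 / total(c)). Cells with zero
    total counts must be filtered beforehand and raise here.
    """
    total = np.asarray(counts.X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("zero-total cell encountered; run cell QC first")
    out = counts.copy()
    X = _dense(out.X).astype(np.float64)
    X = np.log1p(X * (1e6 / total[:, None]))
    out.X = X
    out.uns.setdefault("provenance", []).append("cpm_log1p")
    return out


def _dispersion_norm(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-style normalized dispersion on log-transformed data.

    Mean and dispersion (variance/mean) are computed on the de-logged values,
    then the dispersion is z-scored within bins of similar mean expression.
    """
    Y = np.expm1(X)
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = np.log1p(mean)
    bins = np.digitize(df, np.linspace(df.min(), df.max() + 1e-12, n_bins + 1))
    finite = ~np.isnan(disp)
    g_mu = disp[finite].mean() if finite.any() else 0.0
    g_sd = disp[finite].std(ddof=1) if finite.sum() > 1 else 0.0
    norm = np.full_like(disp, -np.inf)
    for b in np.unique(bins):
        sel = bins == b
        d = disp[sel]
        good = ~np.isnan(d)
        if good.sum() == 0:
            continue
        if good.sum() >= 2 and d[good].std(ddof=1) > 0:
            mu, sd = d[good].mean(), d[good].std(ddof=1)
        else:
            # under-populated or degenerate bin: score against all genes so a
            # lone high-dispersion gene is not silently zeroed out
            mu, sd = g_mu, g_sd
        z = (d - mu) / sd if sd > 0 else np.where(good, 0.0, -np.inf)
        z = np.where(np.isnan(z), -np.inf, z)
        norm[sel] = z
    return norm


def select_hvg(
    expr: ad.AnnData, n_top: int = 2000
) -> tuple[ad.AnnData, list[str]]:
    """Restrict to the `n_top` most variable genes.

    Ranking is by normalized dispersion, descending; ties (and genes with
    undefined dispersion, ranked last) break by gene order in the input, so
    the selection is deterministic.
    """
    if n_top > expr.n_vars:
        raise ValueError(f"n_top={n_top} exceeds gene count {expr.n_vars}")
    norm = _dispersion_norm(_dense(expr.X))
    order = np.argsort(-norm, kind="stable")
    chosen = np.sort(order[:n_top])  # keep original gene order in the output
    out = expr[:, chosen].copy()
    out.uns.setdefault("provenance", []).append(f"hvg_top_{n_top}")
    return out, [expr.var_names[i] for i in chosen]


def preprocess_pipeline(
    counts: ad.AnnData,
    max_total_counts: float = 14_000,
    max_mito_fraction: float = 0.05,
    min_cells: int = 20,
    n_top_genes: int = 2000,
    mito_prefixes=MITO_PREFIXES,
) -> tuple[ad.AnnData, list[QCReport]]:
    """Cells -> genes -> normalize -> HVG with the standard defaults."""
    a, rep_c = qc_filter_cells(counts, max_total_counts, max_mito_fraction, mito_prefixes)
    a, rep_g = qc_filter_genes(a, min_cells)
    a = normalize_cpm_log(a)
    n_top = min(n_top_genes, a.n_vars)
    a, _ = select_hvg(a, n_top)
    return a, [rep_c, rep_g]
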