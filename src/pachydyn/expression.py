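"""Cell QC, normalization, HVG selection, pseudobulk correlation and DE.

Implements the expression-level accounting around the kinetic analysis:
cells are kept when 200 < genes detected < 8500 and mitochondrial
fraction < 20%; counts are LogNormalized (ln(1 + scale * count /
cell_total), scale 1e4); the top 2000 genes by dispersion are the
highly-variable set; cluster similarity between samples uses Spearman
correlation of per-cluster pseudobulk over the top-3000-SD gene panel;
differential expression between clusters uses a Wilcoxon rank-sum test
with the |log2FC| > 1 and P < 0.01 calling rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

__all__ = [
    "QCThresholds",
    "DEGResult",
    "qc_filter",
    "log_normalize",
    "select_hvg",
    "pseudobulk_correlation",
    "differential_expression",
    "overlap_fractions",
]


@dataclass(frozen=True)
class QCThresholds:
    """Survival bounds: keep min_genes < detected < max_genes, mito < max."""

    min_genes: int = 200
    max_genes: int = 8500
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def qc_filter(cell_meta: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    """Boolean mask of surviving cells.

    A cell survives iff min_genes < genes_detected < max_genes and
    mito_fraction < max_mito_fraction (boundaries are filtered).
    """
    missing = [c for c in ("genes_detected", "mito_fraction") if c not in cell_meta]
    if missing:
        raise ValueError(f"cell_meta lacks required fields: {missing}")
    bad = cell_meta[["genes_detected", "mito_fraction"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            "cells with missing QC fields: "
            + ", ".join(map(str, cell_meta.index[bad][:10]))
        )
    g = cell_meta["genes_detected"].to_numpy()
    m = cell_meta["mito_fraction"].to_numpy()
    return (
        (g > thresholds.min_genes)
        & (g < thresholds.max_genes)
        & (m < thresholds.max_mito_fraction)
    )


def log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """ln(1 + scale * count / cell_total) per cell (LogNormalize)."""
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    return np.log1p(scale * X / totals)


def select_hvg(normalized: np.ndarray, gene_ids, n: int = 2000) -> list[str]:
    """Top-n genes by variance-to-mean dispersion; ties broken by gene id."""
    gene_ids = list(gene_ids)
    if n > len(gene_ids):
        raise ValueError(f"asked for {n} HVGs from {len(gene_ids)} genes")
    X = np.asarray(normalized, dtype=float)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    dispersion = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(len(gene_ids)), key=lambda j: (-dispersion[j], gene_ids[j]))
    return [gene_ids[j] for j in order[:n]]


def pseudobulk_correlation(
    normalized: np.ndarray,
    gene_ids,
    cell_meta: pd.DataFrame,
    n_top: int = 3000,
    panel_sample: str = "WT",
    min_cells: int = 5,
) -> pd.DataFrame:
    """Spearman correlation between per-cluster pseudobulk profiles.

    Pseudobulk is the per-cluster mean of normalized expression, built
    separately per (sample, cluster).  The gene panel is the top
    ``n_top`` genes by standard deviation of the panel sample's
    pseudobulk profiles.  Entries lie in [-1, 1].
    """
    gene_ids = list(gene_ids)
    X = np.asarray(normalized, dtype=float)
    groups = cell_meta.groupby(["sample", "cluster"], sort=True)
    profiles, names = [], []
    for (sample, cluster), idx in groups.indices.items():
        if len(idx) < min_cells:
            continue
        profiles.append(X[idx].mean(axis=0))
        names.append(f"{sample}-{cluster}")
    if len(profiles) < 2:
        raise ValueError("need at least two clusters with enough cells")
    P = np.vstack(profiles)

    panel_rows = [i for i, nm in enumerate(names) if nm.startswith(panel_sample + "-")]
    base = P[panel_rows] if panel_rows else P
    sd = base.std(axis=0)
    k = min(n_top, len(gene_ids))
    panel = np.argsort(-sd, kind="stable")[:k]
    rho = pd.DataFrame(P[:, panel].T, columns=names).corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    return rho


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    direction: str  # up | down | ns


def differential_expression(
    groupA: np.ndarray,
    groupB: np.ndarray,
    gene_ids,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
) -> list[DEGResult]:
    """Per-gene Wilcoxon rank-sum DE of normalized values, A vs B.

    log2 fold change compares group means with pseudocount 1; a gene is
    'up' (in A) iff log2FC > lfc_threshold and P < p_threshold, 'down'
    iff log2FC < -lfc_threshold and P < p_threshold, else 'ns'.
    """
    A = np.asarray(groupA, dtype=float)
    B = np.asarray(groupB, dtype=float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if A.shape[0] < 10 or B.shape[0] < 10:
        raise ValueError("both groups need at least 10 cells")
    gene_ids = list(gene_ids)
    lfc = np.log2((A.mean(axis=0) + 1.0) / (B.mean(axis=0) + 1.0))
    results = []
    for j, gid in enumerate(gene_ids):
        a, b = A[:, j], B[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        if lfc[j] > lfc_threshold and p < p_threshold:
            direction = "up"
        elif lfc[j] < -lfc_threshold and p < p_threshold:
            direction = "down"
        else:
            direction = "ns"
        results.append(DEGResult(gid, float(lfc[j]), p, direction))
    return results


def overlap_fractions(
    setA_up, setB_up, setA_down, setB_down
) -> pd.DataFrame:
    """DEG-overlap accounting: |A∩B| as % of each denominator set.

    Percentages are 100*|A∩B|/|set| rounded to one decimal, reported
    against each of the four sets for the up- and down-regulated
    intersections separately.
    """
    rows = []
    for kind, A, B in (("up", set(setA_up), set(setB_up)),
                       ("down", set(setA_down), set(setB_down))):
        inter = len(A & B)
        for name, S in (("A", A), ("B", B)):
            rows.append(
                {
                    "direction": kind,
                    "denominator": name,
                    "n_overlap": inter,
                    "n_set": len(S),
                    "percent": round(100.0 * inter / len(S), 1) if S else 0.0,
                }
            )
    return pd.DataFrame(rows)
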