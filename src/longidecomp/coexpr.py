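"""Weighted co-expression modules: bicor, signed-hybrid adjacency, TOM,
hierarchical module detection and eigengene merging.

The stage mirrors the WGCNA recipe: a robust biweight midcorrelation between
gene expression profiles, a soft-thresholded signed-hybrid adjacency
(negative correlations contribute nothing), topological overlap to reward
shared neighborhoods, average-linkage clustering of the TOM dissimilarity,
and merging of modules whose eigengenes are nearly collinear.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrich import hypergeom_test
from .gee import bh_fdr

logger = logging.getLogger(__name__)

# WGCNA's conventional module color ordering; "grey" is reserved for
# unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED = "grey"


@dataclasses.dataclass(frozen=True)
class ModuleAssignment:
    """Gene -> module labels plus module eigengenes (samples x modules)."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    merge_cut: float


def _bicor_transform(X: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, np.ndarray]:
    """Median-centered, biweight-weighted, unit-norm rows; flags Pearson fallbacks.

    Returns (G, fallback) where bicor = G G'.  Rows with zero MAD cannot take
    biweights and fall back to a z-scored (Pearson) profile; all-constant
    rows become zero vectors (correlation 0 with any partner).
    """
    n_genes, n_samples = X.shape
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    G = np.zeros_like(X, dtype=float)

    ok = ~fallback
    if ok.any():
        u = (X[ok] - med[ok]) / (9.0 * mad[ok])
        # side-specific capping: rescale each tail so at most max_p_outliers
        # of the points on that side fall beyond |u| = 1 (zero weight)
        if max_p_outliers < 0.5:
            q_lo = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
            q_hi = np.quantile(u, 1 - max_p_outliers, axis=1, keepdims=True)
            scale_lo = np.maximum(-q_lo, 1.0)
            scale_hi = np.maximum(q_hi, 1.0)
            u = np.where(u < 0, u / scale_lo, u / scale_hi)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        g = (X[ok] - med[ok]) * w
        norm = np.sqrt((g**2).sum(axis=1, keepdims=True))
        degenerate = norm[:, 0] == 0
        g = np.divide(g, norm, out=np.zeros_like(g), where=norm > 0)
        G[ok] = g
        if degenerate.any():
            idx = np.flatnonzero(ok)[degenerate]
            fallback[idx] = True

    if fallback.any():
        Xf = X[fallback]
        c = Xf - Xf.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1, keepdims=True))
        G[fallback] = np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)
        logger.info("%d genes used Pearson fallback in bicor", int(fallback.sum()))
    return G, fallback


def bicor_matrix(expr: pd.DataFrame, max_p_outliers: float = 0.1) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (genes x samples input).

    Points are weighted by Tukey biweights around the median, with
    side-specific outlier capping so at most ``max_p_outliers`` of either
    tail is fully down-weighted.  Genes with zero MAD fall back to Pearson
    for their pairs.
    """
    if expr.shape[1] < 4:
        raise ValueError("bicor needs at least 4 samples")
    G, _ = _bicor_transform(expr.to_numpy(float), max_p_outliers)
    C = np.clip(G @ G.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=expr.index, columns=expr.index)


def adjacency_signed_hybrid(cor: pd.DataFrame | np.ndarray, beta: float = 5.0):
    """a_ij = cor_ij^beta for positive correlations, else 0; unit diagonal."""
    if beta <= 0:
        raise ValueError("soft power beta must be positive")
    C = cor.to_numpy(float) if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if np.nanmax(np.abs(C)) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    A = np.where(C > 0, np.clip(C, 0, 1) ** beta, 0.0)
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def tom_similarity(adjacency: pd.DataFrame | np.ndarray):
    """Topological overlap: shared-neighbor-weighted similarity in [0, 1]."""
    A = adjacency.to_numpy(float) if isinstance(adjacency, pd.DataFrame) else np.asarray(
        adjacency, float
    )
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1) - np.diag(A)
    # sum over shared neighbors u != i, j of a_iu a_uj (diagonal is 1)
    shared = A @ A - A * (np.diag(A)[None, :] + np.diag(A)[:, None])
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (shared + A) / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)
    return T


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.995
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_module_size`` become "grey"; surviving clusters are
    labeled with the conventional color names in decreasing size order.
    """
    D = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, dtype=object, name="module")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    # deterministic: order by size, ties by smallest cluster id
    ordered = sorted(big.index, key=lambda c: (-big[c], c))
    if not ordered:
        logger.warning("no cluster reached min_module_size=%d; all genes grey", min_module_size)
    for color, cluster in zip(MODULE_COLORS, ordered):
        labels[raw == cluster] = color
    return labels


def module_eigengene(expr: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """First PC over samples of the standardized module submatrix, unit norm.

    Sign is fixed so the eigengene correlates positively with the average
    member profile.
    """
    sub = expr.loc[list(genes)].to_numpy(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    if (Z @ e).sum() < 0:
        e = -e
    return pd.Series(e, index=expr.columns)


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut: float = 0.25
) -> ModuleAssignment:
    """Iteratively merge modules whose eigengene dissimilarity 1 - r < merge_cut.

    The closest pair is merged first and eigengenes recomputed until every
    remaining pair satisfies 1 - r >= merge_cut.  Grey (unassigned) genes are
    never merged.
    """
    labels = labels.copy()
    while True:
        modules = [m for m in labels.unique() if m != UNASSIGNED]
        if len(modules) < 2:
            break
        eig = {m: module_eigengene(expr, labels.index[labels == m]) for m in modules}
        best, best_cor = None, -np.inf
        for i, a in enumerate(modules):
            for b in modules[i + 1 :]:
                r = float(np.corrcoef(eig[a], eig[b])[0, 1])
                if r > best_cor:
                    best_cor, best = r, (a, b)
        if best is None or 1.0 - best_cor >= merge_cut:
            break
        a, b = best
        # absorb the smaller module into the larger one
        if (labels == a).sum() < (labels == b).sum():
            a, b = b, a
        labels[labels == b] = a

    modules = [m for m in labels.unique() if m != UNASSIGNED]
    eigengenes = pd.DataFrame(
        {m: module_eigengene(expr, labels.index[labels == m]) for m in modules},
        index=expr.columns,
    )
    return ModuleAssignment(labels=labels, eigengenes=eigengenes, merge_cut=merge_cut)


def module_set_enrichment(
    assignment: ModuleAssignment | pd.Series,
    flagged_genes_by_stage: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric enrichment of stage-flagged genes within each module.

    BH correction is applied across modules within each stage; the universe
    is the full set of genes carrying a module label (grey included).
    """
    labels = assignment.labels if isinstance(assignment, ModuleAssignment) else assignment
    universe = set(labels.index)
    N = len(universe)
    rows = []
    for stage, gene_list in flagged_genes_by_stage.items():
        genes = set(gene_list) & universe
        n = len(genes)
        stage_rows = []
        for module in sorted(m for m in labels.unique() if m != UNASSIGNED):
            members = set(labels.index[labels == module])
            k = len(genes & members)
            if n == 0:
                continue
            p, fold = hypergeom_test(k, n, len(members), N)
            stage_rows.append(
                {"stage": stage, "module": module, "k": k, "K": len(members), "n": n, "N": N,
                 "p": p, "fold": fold}
            )
        if stage_rows:
            df = pd.DataFrame(stage_rows)
            df["q"] = bh_fdr(df["p"].to_numpy())
            rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["stage", "module", "k", "K", "n", "N", "p", "fold", "q"])
    return pd.concat(rows, ignore_index=True)
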