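"""Cell-type deconvolution of bulk profiles and composition covariates.

Per-sample mixing proportions are estimated by nonnegative least squares
against a user-supplied signature matrix, then summarized by PCA; the PCs
associated with genome-wide expression become covariates for the adjusted
longitudinal screen, absorbing expression variation attributable to shifting
cell composition.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gee import bh_fdr


@dataclasses.dataclass(frozen=True)
class CompositionEstimate:
    """Estimated samples x cell-types proportions (rows on the simplex)."""

    proportions: pd.DataFrame
    residual_norms: pd.Series


@dataclasses.dataclass(frozen=True)
class PcCovariates:
    """PC scores of the composition estimates, zero-mean over samples."""

    scores: pd.DataFrame
    variance_explained: pd.Series
    selected: tuple[int, ...] | None = None


def estimate_proportions(
    bulk_expression: pd.DataFrame, signature: pd.DataFrame
) -> CompositionEstimate:
    """NNLS fit of each bulk sample to the signature columns.

    Both the signature columns and the bulk vector are z-scored over the
    shared genes before solving min ||S x - b||, x >= 0; coefficients are
    mapped back to the linear scale (divided by each column's sd) and
    renormalized to the simplex, yielding relative proportions invariant to
    the bulk vector's scale.
    """
    common = bulk_expression.index.intersection(signature.index)
    if len(common) < signature.shape[1]:
        raise ValueError(
            f"only {len(common)} genes shared between bulk and signature; "
            f"need at least {signature.shape[1]}"
        )
    S = signature.loc[common].to_numpy(float)
    s_mean, s_sd = S.mean(axis=0), S.std(axis=0, ddof=1)
    if (s_sd <= 0).any():
        raise ValueError("signature has a constant column over the shared genes")
    S_z = (S - s_mean) / s_sd

    props, resid = [], []
    for sid in bulk_expression.columns:
        b = bulk_expression.loc[common, sid].to_numpy(float)
        b_sd = b.std(ddof=1)
        if b_sd <= 0:
            props.append(np.full(S.shape[1], 1.0 / S.shape[1]))
            resid.append(np.nan)
            warnings.warn(f"constant bulk profile for sample {sid}; uniform proportions", stacklevel=2)
            continue
        b_z = (b - b.mean()) / b_sd
        x, rnorm = optimize.nnls(S_z, b_z)
        x = x / s_sd  # back to the linear-scale mixing weights (up to b_sd)
        total = x.sum()
        if total <= 0:
            props.append(np.full(S.shape[1], 1.0 / S.shape[1]))
            warnings.warn(f"zero NNLS solution for sample {sid}; uniform proportions", stacklevel=2)
        else:
            props.append(x / total)
        resid.append(float(rnorm))
    return CompositionEstimate(
        proportions=pd.DataFrame(props, index=bulk_expression.columns, columns=signature.columns),
        residual_norms=pd.Series(resid, index=bulk_expression.columns, name="residual_norm"),
    )


def proportion_pcs(estimates: CompositionEstimate | pd.DataFrame) -> PcCovariates:
    """PCA (via SVD) of column-centered proportions; all positive-variance PCs."""
    props = estimates.proportions if isinstance(estimates, CompositionEstimate) else estimates
    if props.shape[0] < 3:
        raise ValueError("need at least 3 samples for composition PCA")
    X = props.to_numpy(float)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.size, bool)
    if not keep.any():
        warnings.warn("proportions constant across samples; no PCs returned", stacklevel=2)
        return PcCovariates(
            scores=pd.DataFrame(index=props.index),
            variance_explained=pd.Series(dtype=float),
        )
    scores = u[:, keep] * s[keep]
    var_exp = s[keep] ** 2 / np.sum(s[keep] ** 2)
    names = [f"PC{i+1}" for i in range(keep.sum())]
    return PcCovariates(
        scores=pd.DataFrame(scores, index=props.index, columns=names),
        variance_explained=pd.Series(var_exp, index=names, name="variance_explained"),
    )


def select_pcs(
    pcs: PcCovariates,
    log_expression: pd.DataFrame,
    fdr: float = 0.05,
    min_genes_fraction: float = 0.05,
) -> tuple[int, ...]:
    """Indices (0-based, variance order) of PCs associated with expression.

    Each gene's log-normalized expression is regressed on one PC score at a
    time; a PC is selected when more than ``min_genes_fraction`` of genes
    reach BH FDR < ``fdr``.
    """
    if not pcs.scores.index.equals(log_expression.columns):
        raise ValueError("PC scores and expression matrix cover different samples")
    n = log_expression.shape[1]
    Y = log_expression.to_numpy(float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((Yc**2).sum(axis=1))
    selected = []
    for j, name in enumerate(pcs.scores.columns):
        x = pcs.scores[name].to_numpy(float)
        xc = x - x.mean()
        x_norm = np.sqrt((xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Yc @ xc) / (y_norm * x_norm)
            r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
            t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[~np.isfinite(p)] = 1.0
        q = bh_fdr(p)
        if np.mean(q < fdr) > min_genes_fraction:
            selected.append(j)
    return tuple(selected)
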