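"""Per-gene longitudinal screens via negative-binomial-variance GEE.

Counts are modeled marginally with a log link and NB variance v(mu) =
mu + alpha mu^2; repeated measures within a subject are handled by a working
correlation (independence or exchangeable) and inference uses the robust
sandwich covariance, which is consistent even when the working correlation is
wrong.  Each gene is screened with a timepoint factor (T0 reference) plus
covariates, a joint Wald test over the timepoint coefficients, and BH FDR
across genes.

The estimating equation solved is

    sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,     mu = exp(X beta + offset)

with D_i = d mu_i / d beta, V_i = A_i^{1/2} R(omega) A_i^{1/2} and A the
diagonal of v(mu).  The sandwich covariance is B^{-1} M B^{-1} with
B = sum_i D' V^{-1} D and M = sum_i D' V^{-1} r r' V^{-1} D.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclasses.dataclass
class GeeFit:
    """One gene's marginal-model fit."""

    beta: pd.Series
    cov: np.ndarray  # robust sandwich covariance
    corstr: str
    omega: float  # exchangeable working correlation (0 under independence)
    alpha: float  # NB dispersion used in the variance function
    converged: bool
    n_iter: int


def estimate_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion: alpha = max(0, sum((y-mu)^2 - mu)/sum(mu^2))."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    denom = np.sum(mu**2)
    if denom <= 0:
        return 0.0
    return float(max(0.0, np.sum((y - mu) ** 2 - mu) / denom))


def _exchangeable_omega(resid_std: np.ndarray, groups: np.ndarray, n_params: int) -> float:
    """Moment estimator of the exchangeable correlation from standardized residuals."""
    n_obs = resid_std.size
    scale = np.sum(resid_std**2) / max(n_obs - n_params, 1)
    num = 0.0
    n_pairs = 0
    max_size = 1
    for g in np.unique(groups):
        e = resid_std[groups == g]
        m = e.size
        max_size = max(max_size, m)
        if m < 2:
            continue
        num += (e.sum() ** 2 - np.sum(e**2)) / 2.0
        n_pairs += m * (m - 1) // 2
    if n_pairs <= n_params or scale <= 0:
        return 0.0
    omega = num / ((n_pairs - n_params) * scale)
    lower = -1.0 / (max_size - 1) + 1e-6 if max_size > 1 else 0.0
    return float(np.clip(omega, lower, 0.99))


def fit_gee(
    y: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    cluster_ids: Sequence,
    corstr: str = "independence",
    offset: np.ndarray | None = None,
    alpha: float | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GeeFit:
    """Solve the GEE for one response vector.

    When ``alpha`` is None the NB dispersion is estimated once, by the moment
    estimator applied to an initial independence fit, and then held fixed.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, float)
    if (y < 0).any():
        raise ValueError("response must be nonnegative counts")
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, float)
    groups = pd.factorize(np.asarray(cluster_ids))[0]
    if corstr not in ("independence", "exchangeable"):
        raise ValueError(f"unknown working correlation: {corstr}")

    if alpha is None:
        init = fit_gee(y, X, cluster_ids, "independence", offset, alpha=0.0, tol=tol, maxiter=maxiter)
        mu0 = np.exp(np.clip(X @ init.beta.to_numpy() + offset, -30, 30))
        alpha = estimate_dispersion(y, mu0)

    # start from a least-squares fit on the log scale
    z = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)

    group_index = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    converged = False
    omega = 0.0
    it = 0
    singular = False
    for it in range(1, maxiter + 1):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        v = mu + alpha * mu**2
        resid = y - mu
        resid_std = resid / np.sqrt(v)
        if corstr == "exchangeable":
            omega = _exchangeable_omega(resid_std, groups, p)

        if corstr == "independence" or omega == 0.0:
            # V is diagonal: weighted least squares update
            w = mu**2 / v
            B = X.T @ (w[:, None] * X)
            score = X.T @ (mu / v * resid)
        else:
            B = np.zeros((p, p))
            score = np.zeros(p)
            for idx in group_index:
                m = idx.size
                Ai = np.sqrt(v[idx])
                R = np.full((m, m), omega) + (1 - omega) * np.eye(m)
                Vi = R * np.outer(Ai, Ai)
                Di = mu[idx, None] * X[idx]
                try:
                    VinvD = np.linalg.solve(Vi, Di)
                    Vinvr = np.linalg.solve(Vi, resid[idx])
                except np.linalg.LinAlgError:
                    continue
                B += Di.T @ VinvD
                score += Di.T @ Vinvr
        try:
            delta = np.linalg.solve(B, score)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # sandwich covariance at the final iterate
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    v = mu + alpha * mu**2
    resid = y - mu
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for idx in group_index:
        m = idx.size
        Ai = np.sqrt(v[idx])
        if corstr == "exchangeable" and omega != 0.0:
            R = np.full((m, m), omega) + (1 - omega) * np.eye(m)
            Vi = R * np.outer(Ai, Ai)
        else:
            Vi = np.diag(v[idx])
        Di = mu[idx, None] * X[idx]
        try:
            VinvD = np.linalg.solve(Vi, Di)
            Vinvr = np.linalg.solve(Vi, resid[idx])
        except np.linalg.LinAlgError:
            singular = True
            continue
        B += Di.T @ VinvD
        u = Di.T @ Vinvr
        M += np.outer(u, u)
    try:
        Binv = np.linalg.inv(B)
        cov = Binv @ M @ Binv
        cov = (cov + cov.T) / 2.0
    except np.linalg.LinAlgError:
        singular = True
        cov = np.full((p, p), np.nan)

    return GeeFit(
        beta=pd.Series(beta, index=names, name="beta"),
        cov=cov,
        corstr=corstr,
        omega=float(omega),
        alpha=float(alpha),
        converged=bool(converged and not singular),
        n_iter=it,
    )


def wald_joint_test(
    fit: GeeFit,
    coefficient_indices: Sequence[int],
    n_clusters: int | None = None,
    reference: str = "f",
) -> tuple[float, int, float]:
    """Joint Wald test that the selected coefficients are all zero.

    W = b' C^{-1} b on the sandwich covariance.  With ``reference="f"``
    (default when ``n_clusters`` is given) the p-value uses the
    Hotelling-style F reference, F(df, K - df) after scaling W by
    (K - df)/(df (K - 1)) for K clusters: the sandwich is estimated from only
    K cluster score vectors, and the naive chi-square reference is badly
    anticonservative for joint tests at repeated-measures cohort sizes.
    ``reference="chisq"`` (or K <= df) gives the plain chi-square p.
    """
    idx = np.asarray(list(coefficient_indices), int)
    b = fit.beta.to_numpy()[idx]
    C = fit.cov[np.ix_(idx, idx)]
    df = idx.size
    if not np.all(np.isfinite(C)):
        return np.nan, df, np.nan
    try:
        W = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError:
        return np.nan, df, np.nan
    if W < 0:
        return np.nan, df, np.nan
    if reference == "f" and n_clusters is not None and n_clusters > df + 1:
        fstat = W * (n_clusters - df) / (df * (n_clusters - 1))
        return W, df, float(stats.f.sf(fstat, df, n_clusters - df))
    return W, df, float(stats.chi2.sf(W, df))


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are propagated."""
    p = np.asarray(pvalues, float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def build_design(
    metadata: pd.DataFrame,
    baseline: str = "T0",
    covariates: Sequence[str] = ("age",),
    pc_scores: pd.DataFrame | None = None,
    timepoint_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with intercept, timepoint indicators and covariates.

    Returns the design and the names of the timepoint indicator columns
    (targets of the joint Wald test).  Continuous covariates are centered.
    """
    tps = list(timepoint_order) if timepoint_order is not None else list(
        pd.unique(metadata["timepoint"])
    )
    if baseline not in tps:
        raise ValueError(f"baseline {baseline} not among timepoints {tps}")
    cols = {"intercept": np.ones(len(metadata))}
    tp_names = []
    for tp in tps:
        if tp == baseline:
            continue
        name = f"tp_{tp}"
        cols[name] = (metadata["timepoint"] == tp).to_numpy(float)
        tp_names.append(name)
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        vals = metadata[cov].to_numpy(float)
        cols[cov] = vals - vals.mean()
    design = pd.DataFrame(cols, index=metadata.index)
    if pc_scores is not None:
        pc_scores = pc_scores.loc[metadata.index]
        for name in pc_scores.columns:
            design[name] = pc_scores[name].to_numpy(float)
    return design, tp_names


def run_screen(
    counts: pd.DataFrame,
    factors,
    metadata: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    corstr: str = "independence",
    covariates: Sequence[str] = ("age",),
    baseline: str = "T0",
    timepoint_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit the GEE screen for every gene and BH-correct across genes.

    ``factors`` is a :class:`~longidecomp.preprocess.NormFactors`; the linear
    predictor includes offset ln(N_k f_k) so coefficients are on the
    normalized (relative-abundance) scale.  The returned table has one row
    per gene with the joint Wald test over timepoints and per-timepoint
    log2 fold changes versus the baseline.
    """
    metadata = metadata.loc[counts.columns]
    design, tp_names = build_design(metadata, baseline, covariates, pcs, timepoint_order)
    offset = np.log(factors.effective_lib_sizes.loc[counts.columns].to_numpy(float))
    cluster = metadata["subject_id"].to_numpy()
    n_clusters = len(pd.unique(cluster))
    tp_idx = [design.columns.get_loc(n) for n in tp_names]
    variant = "adjusted" if pcs is not None and pcs.shape[1] > 0 else "unadjusted"

    rows = []
    Y = counts.to_numpy(float)
    for gi, gene in enumerate(counts.index):
        fit = fit_gee(Y[gi], design, cluster, corstr=corstr, offset=offset)
        if fit.converged:
            W, df, p = wald_joint_test(fit, tp_idx, n_clusters=n_clusters)
        else:
            W, df, p = np.nan, len(tp_idx), np.nan
        row = {
            "gene": gene,
            "variant": variant,
            "W": W,
            "df": df,
            "p": p,
            "converged": fit.converged,
            "alpha": fit.alpha,
            "omega": fit.omega,
        }
        for name in tp_names:
            row[f"log2FC_{name[3:]}"] = fit.beta[name] / LN2
        rows.append(row)
    res = pd.DataFrame(rows).set_index("gene")
    n_failed = int((~res["converged"]).sum())
    if n_failed:
        logger.warning("%d genes failed GEE convergence; excluded from FDR", n_failed)
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res
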