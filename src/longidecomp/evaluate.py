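"""Recovery and calibration benchmarks run against known ground truth.

Every function here *recomputes* a quantity by running the package on freshly
generated data: oracle agreement (GEE vs an independent NB-GLM, TMM/BH/
hypergeometric/bicor vs literal reference transcriptions), deconvolution
error, null-screen calibration, mechanism recovery, postpartum reversion and
module recovery.  The reference transcriptions are deliberately naive,
separate implementations kept for cross-checking only.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import coexpr, deconv, effects, enrich, gee, preprocess, synth
from .config import CohortConfig, PipelineConfig
from .pipeline import simulate_cohort

BASE_ALPHA = CohortConfig().baseline_alpha


# ---------------------------------------------------------------- oracles

def reference_tmm_factor(y_k, y_r, trim_m=0.30, trim_a=0.05) -> float:
    """Naive transcription of the TMM definition for one sample pair."""
    y_k = np.asarray(y_k, float)
    y_r = np.asarray(y_r, float)
    n_k, n_r = y_k.sum(), y_r.sum()
    pos = (y_k > 0) & (y_r > 0)
    y_k, y_r = y_k[pos], y_r[pos]
    m = np.log2((y_k / n_k) / (y_r / n_r))
    a = 0.5 * np.log2((y_k / n_k) * (y_r / n_r))
    w = 1.0 / ((n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r))
    n = len(m)

    def keep(v, trim):
        cut = int(np.floor(n * trim))
        order = np.argsort(np.argsort(v, kind="stable"), kind="stable")
        return (order >= cut) & (order < n - cut)

    sel = keep(m, trim_m) & keep(a, trim_a)
    return float(2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))


def reference_bh(p) -> np.ndarray:
    """Double-loop BH step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sp = p[order]
    q = np.empty(m)
    for i in range(m):
        best = min(sp[j] * m / (j + 1) for j in range(i, m))
        q[order[i]] = min(best, 1.0)
    return q


def reference_hypergeom(k, n, K, N) -> float:
    """Exact upper tail with rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for kk in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, kk) * math.comb(N - K, n - kk), total)
    return float(acc)


def reference_bicor_pair(x, y, max_p_outliers=0.1) -> float:
    """Per-pair transcription of the biweight midcorrelation."""

    def g(v):
        v = np.asarray(v, float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        lo = np.quantile(u, max_p_outliers)
        hi = np.quantile(u, 1 - max_p_outliers)
        u = np.where(u < 0, u / max(-lo, 1.0), u / max(hi, 1.0))
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    gx, gy = g(x), g(y)
    return float(np.sum(gx * gy) / np.sqrt(np.sum(gx**2) * np.sum(gy**2)))


def gee_vs_glm_max_diff(n_genes: int = 100, seed: int = 0) -> float:
    """Max |coef difference| between the GEE (singleton clusters,
    independence) and statsmodels' IRLS NB-GLM over simulated genes."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_genes):
        n = 60
        X = np.column_stack(
            [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n).astype(float)]
        )
        mu = np.exp(X @ np.array([3.0, 0.4, -0.6]))
        alpha = 0.25
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        fit = gee.fit_gee(y, X, np.arange(n), alpha=alpha)
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit(tol=1e-12)
        worst = max(worst, float(np.max(np.abs(fit.beta.to_numpy() - glm.params))))
    return worst


def tmm_vs_reference_max_diff(seed: int = 0) -> float:
    """40-gene two-sample fixture (half of B near-doubled, distinct M/A)."""
    rng = np.random.default_rng(seed)
    a = rng.integers(50, 2000, size=40)
    b = a.copy()
    b[:20] = 2 * b[:20] + rng.integers(1, 9, size=20)
    b[20:] = b[20:] + rng.integers(1, 9, size=20)
    counts = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(40)])
    nf = preprocess.tmm_factors(counts)
    other = [c for c in counts.columns if c != nf.reference][0]
    expected = reference_tmm_factor(counts[other], counts[nf.reference])
    observed = nf.factors[other] / nf.factors[nf.reference]
    return float(abs(observed - expected))


def bh_vs_reference_max_diff(n_vectors: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        worst = max(worst, float(np.max(np.abs(gee.bh_fdr(p) - reference_bh(p)))))
    return worst


def hypergeom_toy() -> tuple[float, float]:
    """The printed toy: N=10, K=4, n=3, k=2 (exact p = 1/3)."""
    p, fold = enrich.hypergeom_test(2, 3, 4, 10)
    return p, abs(p - reference_hypergeom(2, 3, 4, 10))


def bicor_vs_reference_max_diff(seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(rng.normal(size=(12, 30)))
    C = coexpr.bicor_matrix(expr)
    X = expr.to_numpy()
    worst = 0.0
    for i, j in combinations(range(12), 2):
        worst = max(worst, float(abs(C.iloc[i, j] - reference_bicor_pair(X[i], X[j]))))
    return worst


# ------------------------------------------------------------- recovery

def deconv_noiseless_max_error(seed: int = 0) -> float:
    """Noiseless two-type mixtures must be recovered to solver tolerance."""
    sig = synth.generate_signature(120, 3, markers_per_type=10, marker_fold=20, seed=seed).values
    worst = 0.0
    for w1 in (0.3, 0.5, 0.9):
        mix = w1 * sig.iloc[:, 0] + (1 - w1) * sig.iloc[:, 1]
        est = deconv.estimate_proportions(pd.DataFrame({"s": mix}), sig)
        target = np.array([w1, 1 - w1, 0.0])
        worst = max(worst, float(np.max(np.abs(est.proportions.loc["s"].to_numpy() - target))))
    return worst


def deconv_cohort_mae(seed: int = 0, phi: float = 0.05) -> float:
    """Max per-type mean absolute error on a default-design cohort."""
    cfg = PipelineConfig(seed=seed)
    sig, comp, plan, _, _, _ = simulate_cohort(cfg)
    plan = synth.RegulationPlan(
        rho=plan.rho, tau=plan.tau,
        phi=pd.Series(phi, index=plan.phi.index), lib_sizes=plan.lib_sizes,
    )
    counts, meta, truth = synth.generate_counts(sig, comp, plan, seed=seed + 7)
    fac = preprocess.tmm_factors(counts)
    cpm = preprocess.cpm_normalized(counts, fac)
    est = deconv.estimate_proportions(cpm, sig.values)
    truth_p = truth.proportions.loc[est.proportions.index, est.proportions.columns]
    return float((est.proportions - truth_p).abs().mean().max())


def _null_cohort(seed: int, n_genes: int = 500):
    sig = synth.generate_signature(n_genes, 8, markers_per_type=10, seed=seed)
    comp = synth.generate_compositions(
        14, ("T0", "T1", "T2", "T3", "PP3"),
        dict(zip(sig.cell_types, BASE_ALPHA)), logit_shifts=None, seed=seed + 1,
    )
    plan = synth.default_regulation_plan(sig, comp, regulated_fraction=0.0, seed=seed + 2)
    return synth.generate_counts(sig, comp, plan, seed=seed + 3)


def null_calibration(seed: int = 0, n_genes: int = 500) -> tuple[float, float]:
    """(Wald p<0.05 rate, BH q<0.05 rate) on a global-null cohort."""
    counts, meta, _ = _null_cohort(seed, n_genes)
    filt = preprocess.filter_low_expression(counts)
    fac = preprocess.tmm_factors(filt)
    scr = gee.run_screen(filt, fac, meta)
    ok = scr["converged"]
    return float((scr.loc[ok, "p"] < 0.05).mean()), float((scr.loc[ok, "q"] < 0.05).mean())


def _recovery_cohort_config(seed: int) -> PipelineConfig:
    # composition shift delta = 1.0 on one type across the trimesters;
    # regulation |rho| = ln 4 on a disjoint gene set; reverts postpartum
    return PipelineConfig(
        cohort=CohortConfig(
            shift_schedule=(("T1", 1.0), ("T2", 1.0), ("T3", 1.0)),
            regulation_effect=math.log(4.0),
        ),
        seed=seed,
    )


def run_mechanism_recovery(seed: int) -> dict:
    """Full path on one planted cohort; returns truth-vs-predicted metrics."""
    cfg = _recovery_cohort_config(seed)
    sig, comp, plan, counts, meta, truth = simulate_cohort(cfg)
    t = cfg.thresholds
    filt = preprocess.filter_low_expression(counts)
    fac = preprocess.tmm_factors(filt)
    cpm = preprocess.cpm_normalized(filt, fac)
    log_cpm = preprocess.cpm_normalized(filt, fac, log=True)
    est = deconv.estimate_proportions(cpm, sig.values)
    pcs = deconv.proportion_pcs(est)
    selected = deconv.select_pcs(pcs, log_cpm, fdr=t.pc_fdr,
                                 min_genes_fraction=t.pc_min_genes_fraction)
    pc_scores = pcs.scores.iloc[:, list(selected)]
    scr_u = gee.run_screen(filt, fac, meta)
    scr_a = gee.run_screen(filt, fac, meta, pcs=pc_scores if len(selected) else None)
    calls_u = effects.call_pregnancy_associated(scr_u, fdr=t.fdr, fc=t.fc)
    calls_a = effects.call_pregnancy_associated(scr_a, fdr=t.fdr, fc=t.fc)
    mech = effects.classify_mechanism(calls_u, calls_a)

    tt = truth.table.loc[mech.index, "class"]
    mapping = {"null": "none", "composition": "composition",
               "regulation": "regulation", "mixed": "mixed"}
    recalls = {}
    for cls, target in mapping.items():
        mask = tt == cls
        if mask.any():
            recalls[cls] = float((mech.loc[mask, "class"] == target).mean())
    reg_genes = tt.index[tt == "regulation"]
    return {
        "recalls": recalls,
        "balanced_accuracy": float(np.mean(list(recalls.values()))),
        "regulation_sensitivity": float(calls_a.loc[reg_genes, "flagged"].mean()),
        "composition_recall": recalls.get("composition", np.nan),
    }


def mechanism_recovery(seeds) -> dict:
    """Averages of :func:`run_mechanism_recovery` over several cohorts."""
    runs = [run_mechanism_recovery(s) for s in seeds]
    return {
        "balanced_accuracy": float(np.mean([r["balanced_accuracy"] for r in runs])),
        "regulation_sensitivity": float(np.mean([r["regulation_sensitivity"] for r in runs])),
        "composition_recall": float(np.nanmean([r["composition_recall"] for r in runs])),
        "runs": runs,
    }


def reversion(seed: int = 0) -> tuple[float, int]:
    """Pearson r between pregnancy and postpartum changes on a reverting cohort."""
    cfg = PipelineConfig(seed=seed)  # defaults revert at PP3
    sig, comp, plan, counts, meta, truth = simulate_cohort(cfg)
    filt = preprocess.filter_low_expression(counts)
    fac = preprocess.tmm_factors(filt)
    scr_u = gee.run_screen(filt, fac, meta)
    scr_t3 = gee.run_screen(filt, fac, meta, baseline="T3")
    return effects.reversion_correlation(scr_u, scr_t3)


def module_recovery_rand_index(seed: int = 0) -> float:
    """Planted two-block structure through the full co-expression chain."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(2):
        common = rng.normal(size=40)
        for _ in range(60):
            rows.append(np.sqrt(0.8) * common + np.sqrt(0.2) * rng.normal(size=40))
            labels.append(b)
    expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(120)])
    C = coexpr.bicor_matrix(expr)
    A = coexpr.adjacency_signed_hybrid(C, beta=5)
    T = coexpr.tom_similarity(A)
    det = coexpr.detect_modules(T, min_module_size=30)
    asg = coexpr.merge_modules(expr, det, merge_cut=0.25)
    truth = np.asarray(labels)
    pred = asg.labels.to_numpy()
    agree = total = 0
    for i, j in combinations(range(len(truth)), 2):
        agree += (truth[i] == truth[j]) == (pred[i] == pred[j])
        total += 1
    return agree / total
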