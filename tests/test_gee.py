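"""GEE solver correctness: GLM oracle equivalence, dispersion moments,
Wald closed forms, BH against brute force, and screen-level recovery."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from longidecomp import gee, preprocess


class TestDispersion:
    def test_zero_when_residuals_match_poisson(self):
        mu = np.full(50, 20.0)
        assert gee.estimate_dispersion(mu, mu) == 0.0

    def test_single_observation_equal_to_mean(self):
        assert gee.estimate_dispersion(np.array([5.0]), np.array([5.0])) == 0.0

    def test_moment_consistency_on_nb_draws(self, rng):
        alpha = 0.2
        mu = np.full(10_000, 100.0)
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        est = gee.estimate_dispersion(y, mu)
        assert 0.18 <= est <= 0.22


class TestFitGee:
    def test_intercept_only_constant_response(self):
        y = np.full(12, 7.0)
        X = np.ones((12, 1))
        fit = gee.fit_gee(y, X, np.arange(12))
        assert fit.converged
        np.testing.assert_allclose(fit.beta.iloc[0], math.log(7.0), atol=1e-8)

    def test_singleton_clusters_match_nb_glm(self, rng):
        # independence + one observation per cluster == ordinary NB GLM
        worst = 0.0
        for _ in range(20):
            n = 60
            X = np.column_stack(
                [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n).astype(float)]
            )
            mu = np.exp(X @ np.array([3.0, 0.4, -0.6]))
            alpha = 0.25
            y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            fit = gee.fit_gee(y, X, np.arange(n), alpha=alpha)
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit(tol=1e-12)
            worst = max(worst, np.max(np.abs(fit.beta.to_numpy() - glm.params)))
        assert worst < 1e-6

    def test_offset_shifts_intercept_exactly(self):
        y = np.full(10, 40.0)
        X = np.ones((10, 1))
        off = np.full(10, math.log(4.0))
        fit = gee.fit_gee(y, X, np.arange(10), offset=off)
        np.testing.assert_allclose(fit.beta.iloc[0], math.log(10.0), atol=1e-8)

    def test_exchangeable_omega_within_valid_range(self, rng):
        subj = np.repeat(np.arange(14), 5)
        tp = np.tile(np.arange(5), 14)
        X = np.column_stack([np.ones(70)] + [(tp == t).astype(float) for t in range(1, 5)])
        b = rng.normal(0, 0.4, 14)
        mu = 100 * np.exp(b[subj])
        y = rng.negative_binomial(5, 5 / (5 + mu))
        fit = gee.fit_gee(y, X, subj, corstr="exchangeable")
        assert fit.converged
        assert -1 / 4 < fit.omega < 1
        assert fit.omega > 0  # shared subject effect induces positive correlation

    def test_sandwich_covariance_symmetric_psd(self, rng):
        subj = np.repeat(np.arange(10), 3)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.poisson(50, 30).astype(float)
        fit = gee.fit_gee(y, X, subj)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(fit.cov).min() > -1e-10

    def test_timepoint_effect_recovery(self, rng):
        # mean of beta_T2 over 200 simulated genes within ln 2 +/- 0.05
        n_subj, n_tp = 14, 3
        subj = np.repeat(np.arange(n_subj), n_tp)
        tp = np.tile(np.arange(n_tp), n_subj)
        X = np.column_stack([np.ones(n_subj * n_tp)] + [(tp == t).astype(float) for t in (1, 2)])
        betas = []
        for _ in range(200):
            b = rng.normal(0, 0.3, n_subj)
            mu = 150 * np.exp(b[subj] + math.log(2.0) * (tp == 2))
            y = rng.negative_binomial(10, 10 / (10 + mu))
            fit = gee.fit_gee(y, X, subj)
            if fit.converged:
                betas.append(fit.beta.iloc[2])
        assert abs(np.mean(betas) - math.log(2.0)) < 0.05

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            gee.fit_gee(np.array([-1.0, 2.0]), np.ones((2, 1)), [0, 1])


class TestWald:
    def _fit_with_cov(self, beta, cov):
        f = gee.GeeFit(
            beta=pd.Series(beta), cov=np.asarray(cov, float), corstr="independence",
            omega=0.0, alpha=0.0, converged=True, n_iter=1,
        )
        return f

    def test_zero_coefficients_give_p_one(self):
        fit = self._fit_with_cov([0.0, 0.0], np.eye(2))
        W, df, p = fit_result = gee.wald_joint_test(fit, [0, 1], reference="chisq")
        assert W == 0 and df == 2 and p == 1.0

    def test_identity_covariance_closed_form(self):
        # beta=(1,0), C=I: W=1, df=2, chi-square survival = exp(-1/2)
        fit = self._fit_with_cov([1.0, 0.0], np.eye(2))
        W, df, p = gee.wald_joint_test(fit, [0, 1], reference="chisq")
        assert W == pytest.approx(1.0)
        assert p == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_f_reference_more_conservative_than_chisq(self):
        fit = self._fit_with_cov([1.0, 0.5], np.eye(2) * 0.1)
        _, _, p_chi = gee.wald_joint_test(fit, [0, 1], reference="chisq")
        _, _, p_f = gee.wald_joint_test(fit, [0, 1], n_clusters=14, reference="f")
        assert p_f > p_chi

    def test_singular_submatrix_yields_missing_p(self):
        fit = self._fit_with_cov([1.0, 1.0], np.ones((2, 2)))
        W, df, p = gee.wald_joint_test(fit, [0, 1])
        assert math.isnan(p)


def bh_bruteforce(p):
    """Double-loop BH: q_i = min over j with p_j >= p_i of p_j * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        best = np.inf
        for j in range(i, m):
            best = min(best, sorted_p[j] * m / (j + 1))
        q[order[i]] = min(best, 1.0)
    return q


class TestBhFdr:
    def test_worked_example(self):
        q = gee.bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_and_tied_pvalues(self):
        np.testing.assert_allclose(gee.bh_fdr(np.array([0.2])), [0.2])
        np.testing.assert_allclose(gee.bh_fdr(np.full(5, 0.07)), np.full(5, 0.07))

    def test_matches_bruteforce_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(40):
            p = rng.uniform(size=rng.integers(1, 60))
            q = gee.bh_fdr(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_nan_propagation(self):
        q = gee.bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert math.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gee.bh_fdr(np.array([0.5, 1.5]))

    def test_q_values_monotone_in_sorted_p_order(self, rng):
        p = rng.uniform(size=200)
        q = gee.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestRunScreen:
    def test_parity_adjustment_leaves_statistics_nearly_unchanged(self, default_cohort):
        sig, comp, plan, counts, meta, truth = default_cohort
        sub = counts.iloc[:150]
        fac = preprocess.tmm_factors(sub)
        base = gee.run_screen(sub, fac, meta)
        with_parity = gee.run_screen(sub, fac, meta, covariates=("age", "parity"))
        ok = base["converged"] & with_parity["converged"]
        r = stats.pearsonr(base.loc[ok, "W"], with_parity.loc[ok, "W"]).statistic
        assert r > 0.95

    def test_regulated_genes_detected(self, default_cohort):
        sig, comp, plan, counts, meta, truth = default_cohort
        reg = truth.table.index[truth.table["class"] == "regulation"]
        fac = preprocess.tmm_factors(counts)
        scr = gee.run_screen(counts.loc[reg], fac, meta)
        # q computed within this subset; all carry an FC-4 planted effect
        assert (scr["p"] < 0.01).mean() >= 0.8

    def test_variant_labeling(self, default_cohort):
        sig, comp, plan, counts, meta, truth = default_cohort
        sub = counts.iloc[:20]
        fac = preprocess.tmm_factors(sub)
        unadj = gee.run_screen(sub, fac, meta)
        pcs = pd.DataFrame({"PC1": np.linspace(-1, 1, sub.shape[1])}, index=sub.columns)
        adj = gee.run_screen(sub, fac, meta, pcs=pcs)
        assert set(unadj["variant"]) == {"unadjusted"}
        assert set(adj["variant"]) == {"adjusted"}
        for tp in ("T1", "T2", "T3", "PP3"):
            assert f"log2FC_{tp}" in unadj.columns
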