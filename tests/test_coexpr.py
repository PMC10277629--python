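"""Co-expression stage: bicor oracle, adjacency/TOM algebra, module recovery."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from longidecomp import coexpr


def bicor_pair_bruteforce(x, y, max_p_outliers=0.1):
    """Literal per-pair transcription of the biweight midcorrelation."""

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        q_lo = np.quantile(u, max_p_outliers)
        q_hi = np.quantile(u, 1 - max_p_outliers)
        u = np.where(u < 0, u / max(-q_lo, 1.0), u / max(q_hi, 1.0))
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    gx, gy = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return np.sum(gx * gy) / np.sqrt(np.sum(gx**2) * np.sum(gy**2))


def rand_index(a, b):
    a, b = np.asarray(a), np.asarray(b)
    agree = total = 0
    for i, j in combinations(range(len(a)), 2):
        agree += (a[i] == a[j]) == (b[i] == b[j])
        total += 1
    return agree / total


class TestBicor:
    def test_self_and_negated_correlation(self, rng):
        x = rng.normal(size=30)
        expr = pd.DataFrame([x, -x], index=["a", "b"])
        C = coexpr.bicor_matrix(expr)
        assert C.loc["a", "a"] == pytest.approx(1.0)
        assert C.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matrix_matches_bruteforce(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 25)))
        C = coexpr.bicor_matrix(expr)
        X = expr.to_numpy()
        for i, j in combinations(range(8), 2):
            expected = bicor_pair_bruteforce(X[i], X[j])
            assert C.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_robust_to_gross_outlier(self, rng):
        # 19 clean points on a known correlation plus one gross outlier:
        # bicor stays closer to the clean-point correlation than Pearson
        n = 19
        z = rng.normal(size=n)
        x = np.append(z + 0.3 * rng.normal(size=n), 0.0)
        y = np.append(z + 0.3 * rng.normal(size=n), 25.0)
        true_cor = np.corrcoef(x[:n], y[:n])[0, 1]
        expr = pd.DataFrame([x, y], index=["a", "b"])
        bic = coexpr.bicor_matrix(expr).loc["a", "b"]
        pear = np.corrcoef(x, y)[0, 1]
        assert abs(bic - true_cor) < abs(pear - true_cor)

    def test_close_to_pearson_on_gaussian_data(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 60)))
        C = coexpr.bicor_matrix(expr)
        P = np.corrcoef(expr.to_numpy())
        diffs = np.abs(C.to_numpy() - P)[np.triu_indices(10, 1)]
        assert np.median(diffs) < 0.05

    def test_constant_gene_falls_back_to_zero_correlation(self, rng):
        expr = pd.DataFrame([np.full(20, 3.0), rng.normal(size=20)], index=["const", "x"])
        C = coexpr.bicor_matrix(expr)
        assert C.loc["const", "x"] == pytest.approx(0.0, abs=1e-12)
        assert C.loc["const", "const"] == 1.0

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            coexpr.bicor_matrix(pd.DataFrame(np.ones((3, 3))))


class TestAdjacency:
    def test_signed_hybrid_values(self):
        cor = np.array([[1.0, -0.5, 0.8], [-0.5, 1.0, 1.0], [0.8, 1.0, 1.0]])
        A = coexpr.adjacency_signed_hybrid(cor, beta=5)
        assert A[0, 1] == 0.0
        assert A[0, 2] == pytest.approx(0.8**5)
        assert A[1, 2] == 1.0 and A[0, 0] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            coexpr.adjacency_signed_hybrid(np.eye(2), beta=-1)
        with pytest.raises(ValueError):
            coexpr.adjacency_signed_hybrid(np.full((2, 2), 1.5))


class TestTom:
    def test_triangle_of_full_adjacency(self):
        A = np.ones((3, 3))
        T = coexpr.tom_similarity(A)
        # shared neighbor contributes 1, k=2: (1 + 1)/(2 + 1 - 1) = 1
        assert T[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_without_shared_neighbors(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.0
        T = coexpr.tom_similarity(A)
        assert T[0, 1] == 0.0

    def test_symmetric_bounded_on_random_adjacencies(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            C = rng.uniform(-1, 1, size=(n, n))
            C = (C + C.T) / 2
            A = coexpr.adjacency_signed_hybrid(C, beta=3)
            T = coexpr.tom_similarity(A)
            assert np.allclose(T, T.T)
            assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            coexpr.tom_similarity(A)


def planted_expression(rng, sizes=(60, 60), n_samples=40, within=0.8):
    rows, labels = [], []
    for b, size in enumerate(sizes):
        common = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(np.sqrt(within) * common + np.sqrt(1 - within) * rng.normal(size=n_samples))
            labels.append(b)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.asarray(labels)


def modules_from_expression(expr, beta=5.0, min_module_size=30, merge_cut=0.25):
    C = coexpr.bicor_matrix(expr)
    A = coexpr.adjacency_signed_hybrid(C, beta=beta)
    T = coexpr.tom_similarity(A)
    labels = coexpr.detect_modules(T, min_module_size=min_module_size)
    return coexpr.merge_modules(expr, labels, merge_cut=merge_cut)


class TestModules:
    def test_planted_two_block_recovery(self, rng):
        expr, truth = planted_expression(rng)
        asg = modules_from_expression(expr)
        found = asg.labels[asg.labels != coexpr.UNASSIGNED]
        assert found.nunique() == 2
        assert rand_index(truth, asg.labels.to_numpy()) > 0.95

    def test_uncorrelated_genes_stay_grey(self, rng):
        clean = 0
        for _ in range(10):
            expr = pd.DataFrame(rng.normal(size=(50, 30)))
            labels = coexpr.detect_modules(
                coexpr.tom_similarity(
                    coexpr.adjacency_signed_hybrid(coexpr.bicor_matrix(expr), beta=5)
                ),
                min_module_size=30,
            )
            clean += int((labels == coexpr.UNASSIGNED).all())
        assert clean >= 9

    def test_identical_genes_form_single_module(self):
        x = np.sin(np.linspace(0, 7, 24))
        expr = pd.DataFrame([x] * 35, index=[f"g{i}" for i in range(35)])
        labels = coexpr.detect_modules(
            coexpr.tom_similarity(
                coexpr.adjacency_signed_hybrid(
                    pd.DataFrame(np.ones((35, 35)), index=expr.index, columns=expr.index), beta=5
                )
            ),
            min_module_size=30,
        )
        assert (labels == labels.iloc[0]).all() and labels.iloc[0] != coexpr.UNASSIGNED


class TestMerging:
    def test_identical_profiles_merge(self, rng):
        expr, _ = planted_expression(rng, sizes=(40, 40), within=0.95)
        # force both blocks onto the same underlying profile
        expr.iloc[40:] = expr.iloc[:40].to_numpy()
        labels = pd.Series(
            ["turquoise"] * 40 + ["blue"] * 40, index=expr.index, dtype=object
        )
        asg = coexpr.merge_modules(expr, labels, merge_cut=0.25)
        assert asg.labels.nunique() == 1

    def test_distinct_modules_not_merged(self, rng):
        expr, truth = planted_expression(rng, within=0.9)
        labels = pd.Series(np.where(truth == 0, "turquoise", "blue"), index=expr.index)
        asg = coexpr.merge_modules(expr, labels, merge_cut=0.25)
        assert asg.labels.nunique() == 2

    def test_post_merge_eigengene_separation(self, rng):
        expr, _ = planted_expression(rng, sizes=(40, 40, 40), within=0.7)
        asg = modules_from_expression(expr)
        E = asg.eigengenes.to_numpy()
        if E.shape[1] >= 2:
            C = np.corrcoef(E.T)
            off = C[np.triu_indices(E.shape[1], 1)]
            assert (off < 1 - asg.merge_cut + 1e-9).all()

    def test_eigengene_unit_norm_and_sign(self, rng):
        expr, truth = planted_expression(rng, sizes=(30,), within=0.9)
        e = coexpr.module_eigengene(expr, expr.index)
        assert np.linalg.norm(e) == pytest.approx(1.0)
        cors = [np.corrcoef(expr.loc[g], e)[0, 1] for g in expr.index]
        assert np.mean(cors) > 0


class TestModuleEnrichment:
    def test_stage_list_equal_to_module_is_top_hit(self, rng):
        expr, truth = planted_expression(rng)
        asg = modules_from_expression(expr)
        module = asg.labels[asg.labels != coexpr.UNASSIGNED].iloc[0]
        members = list(asg.labels.index[asg.labels == module])
        res = coexpr.module_set_enrichment(asg, {"T1": members})
        best = res.loc[res["p"].idxmin(), "module"]
        assert best == module

    def test_empty_stage_list_gives_empty_table(self, rng):
        expr, _ = planted_expression(rng)
        asg = modules_from_expression(expr)
        res = coexpr.module_set_enrichment(asg, {"T1": []})
        assert res.empty

    def test_null_stage_list_calibrated(self, rng):
        expr, _ = planted_expression(rng, sizes=(40, 40, 40), within=0.6)
        asg = modules_from_expression(expr)
        n_sig = n_tot = 0
        for _ in range(100):
            draw = list(rng.choice(expr.index, 20, replace=False))
            res = coexpr.module_set_enrichment(asg, {"T1": draw})
            n_sig += int((res["p"] < 0.05).sum())
            n_tot += len(res)
        assert n_sig / max(n_tot, 1) <= 0.12
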