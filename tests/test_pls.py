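import itertools
import math

import numpy as np
import pytest
from scipy import linalg, stats

from hippostress import pls


class TestResidualize:
    def test_orthogonal_input_unchanged(self, rng):
        n = 40
        age = rng.uniform(20, 55, n)
        sex = rng.choice(["F", "M"], n)
        X = rng.standard_normal((n, 3))
        # orthogonalize X against the design first
        D = np.column_stack([np.ones(n), age,
                             (sex == "F").astype(float)])
        X = X - D @ np.linalg.lstsq(D, X, rcond=None)[0]
        out = pls.residualize_brain(X, age, sex)
        np.testing.assert_allclose(out, X, atol=1e-10)

    def test_linear_function_of_age_vanishes(self, rng):
        n = 30
        age = rng.uniform(20, 55, n)
        sex = np.array(["F"] * 15 + ["M"] * 15)
        X = np.column_stack([2.0 * age - 7.0, -0.5 * age])
        out = pls.residualize_brain(X, age, sex)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_matches_hat_matrix_oracle(self, rng):
        n = 20
        age = rng.uniform(20, 55, n)
        sex = rng.choice(["F", "M"], n)
        X = rng.standard_normal((n, 3))
        out = pls.residualize_brain(X, age, sex)
        D = np.column_stack([np.ones(n), age, (sex == "F").astype(float)])
        H = D @ np.linalg.inv(D.T @ D) @ D.T
        np.testing.assert_allclose(out, (np.eye(n) - H) @ X, atol=1e-10)

    def test_subject_indicators_absorb_subject_means(self, rng):
        n_subj, reps = 10, 3
        sids = np.repeat([f"S{i}" for i in range(n_subj)], reps)
        age = np.repeat(rng.uniform(20, 55, n_subj), reps)
        sex = np.repeat(rng.choice(["F", "M"], n_subj), reps)
        X = rng.standard_normal((n_subj * reps, 2))
        out = pls.residualize_brain(X, age, sex, subject_ids=sids)
        for i in range(n_subj):
            block = out[i * reps:(i + 1) * reps]
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-9)

    def test_saturated_design_falls_back(self, rng):
        n = 8
        sids = np.array([f"S{i}" for i in range(n)])  # one row per subject
        with pytest.warns(UserWarning, match="saturate"):
            out = pls.residualize_brain(rng.standard_normal((n, 2)),
                                        rng.uniform(20, 55, n),
                                        rng.choice(["F", "M"], n),
                                        subject_ids=sids)
        assert np.isfinite(out).all()


class TestNormalizeWithinGroup:
    def test_single_group_is_zscore(self, rng):
        M = rng.standard_normal((20, 3)) * 5 + 2
        out = pls.normalize_within_group(M, np.zeros(20))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_group_offset_removed(self, rng):
        block = rng.standard_normal((10, 2))
        M = np.vstack([block, block + 100.0])
        groups = np.array([0] * 10 + [1] * 10)
        out = pls.normalize_within_group(M, groups)
        np.testing.assert_allclose(out[:10], out[10:], atol=1e-10)

    def test_per_group_moments(self, rng):
        M = rng.standard_normal((30, 4))
        groups = rng.choice(["a", "b", "c"], 30)
        # ensure every group has >= 2 rows
        groups[:6] = ["a", "a", "b", "b", "c", "c"]
        out = pls.normalize_within_group(M, groups)
        for g in "abc":
            block = out[groups == g]
            np.testing.assert_allclose(block.mean(axis=0), 0, atol=1e-12)
            np.testing.assert_allclose(block.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_zero_variance_column_centered(self, rng):
        M = rng.standard_normal((10, 2))
        M[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero within-group SD"):
            out = pls.normalize_within_group(M, np.zeros(10))
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)

    def test_tiny_group_raises(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            pls.normalize_within_group(np.zeros((3, 1)),
                                       np.array([0, 0, 1]))


class TestPlsFit:
    def test_orthogonal_blocks_zero_singular_values(self):
        # X, Y with exactly zero cross-covariance
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        Y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        res = pls.pls_fit(X, Y)
        np.testing.assert_allclose(res.singular_values, 0.0, atol=1e-12)

    def test_univariate_is_abs_covariance(self, rng):
        x = rng.standard_normal(25)
        y = 0.3 * x + rng.standard_normal(25)
        x, y = x - x.mean(), y - y.mean()  # pls_fit expects centered inputs
        res = pls.pls_fit(x[:, None], y[:, None])
        cov = np.cov(x, y)[0, 1]
        assert res.singular_values[0] == pytest.approx(abs(cov), abs=1e-12)
        assert res.covexp[0] == pytest.approx(100.0)

    def test_matches_dense_svd_oracle(self, rng):
        X = rng.standard_normal((12, 3))
        Y = rng.standard_normal((12, 2))
        res = pls.pls_fit(X, Y)
        R = Y.T @ X / 11.0
        U, s, Vt = linalg.svd(R, full_matrices=False)
        np.testing.assert_allclose(res.singular_values, s, atol=1e-10)
        for i in range(len(s)):
            # equal up to joint sign flip
            du = np.abs(res.behavior_saliences[:, i] @ U[:, i])
            dv = np.abs(res.brain_saliences[:, i] @ Vt[i])
            assert du == pytest.approx(1.0, abs=1e-10)
            assert dv == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self, rng):
        res = pls.pls_fit(rng.standard_normal((15, 4)),
                          rng.standard_normal((15, 3)))
        for i in range(res.behavior_saliences.shape[1]):
            u = res.behavior_saliences[:, i]
            assert u[np.argmax(np.abs(u))] > 0

    def test_covexp_sums_to_100(self, rng):
        res = pls.pls_fit(rng.standard_normal((20, 5)),
                          rng.standard_normal((20, 3)))
        assert res.covexp.sum() == pytest.approx(100.0)
        assert (np.diff(res.singular_values) <= 1e-12).all()

    def test_symmetry_in_arguments(self, rng):
        X = rng.standard_normal((18, 4))
        Y = rng.standard_normal((18, 2))
        s1 = pls.pls_fit(X, Y).singular_values
        s2 = pls.pls_fit(Y, X).singular_values
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_column_permutation_invariance(self, rng):
        X = rng.standard_normal((18, 4))
        Y = rng.standard_normal((18, 3))
        s1 = pls.pls_fit(X, Y).singular_values
        s2 = pls.pls_fit(X[:, ::-1], Y[:, [2, 0, 1]]).singular_values
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_nan_rejected(self):
        X = np.zeros((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            pls.pls_fit(X, np.zeros((5, 2)))

    def test_loading_correlations_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        res = pls.pls_fit(X, Y)
        for j in range(3):
            expect = np.corrcoef(X[:, j], res.brain_scores[:, 0])[0, 1]
            assert res.brain_loadings[j, 0] == pytest.approx(expect, abs=1e-12)


class TestPermutationTest:
    def test_perfect_relation_minimal_p(self, rng):
        X = rng.standard_normal((30, 2))
        Y = X.copy()  # duplicate columns: no permutation can beat s1
        p, q = pls.permutation_test(X, Y, n_perm=1000, seed=0)
        assert p[0] == pytest.approx(1 / 1001)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 2))
        p1, _ = pls.permutation_test(X, Y, n_perm=200, seed=5)
        p2, _ = pls.permutation_test(X, Y, n_perm=200, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            pls.permutation_test(np.zeros((5, 1)), np.zeros((5, 1)), n_perm=0)

    def test_null_p_roughly_uniform(self, rng):
        # Monte-Carlo calibration: p1 over independent X,Y ~ uniform-ish
        ps = []
        for _ in range(300):
            X = rng.standard_normal((12, 2))
            Y = rng.standard_normal((12, 2))
            p, _ = pls.permutation_test(X, Y, n_perm=99,
                                        seed=int(rng.integers(1 << 30)))
            ps.append(p[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_within_group_permutation_supported(self, rng):
        X = rng.standard_normal((20, 2))
        Y = rng.standard_normal((20, 2))
        groups = np.array([0] * 10 + [1] * 10)
        p, _ = pls.permutation_test(X, Y, n_perm=100, seed=2, groups=groups)
        assert ((p > 0) & (p <= 1)).all()


class TestBootstrapLoadings:
    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((25, 3))
        Y = 0.5 * X[:, :2] + rng.standard_normal((25, 2))
        c1 = pls.bootstrap_loadings(X, Y, n_boot=50, seed=9)
        c2 = pls.bootstrap_loadings(X, Y, n_boot=50, seed=9)
        np.testing.assert_array_equal(c1["brain"][0], c2["brain"][0])
        np.testing.assert_array_equal(c1["behavior"][1], c2["behavior"][1])

    def test_noise_free_relation_tight_ci(self, rng):
        # deterministic rank-1 relation: loading correlation is pinned at 1
        n = 200
        t = rng.standard_normal(n)
        X = np.column_stack([t, 2 * t])
        Y = np.column_stack([3 * t])
        cis = pls.bootstrap_loadings(X, Y, n_boot=50, seed=1)
        lo, hi = cis["brain"]
        assert (hi[:, 0] - lo[:, 0] < 1e-8).all()

    def test_requires_min_rows(self, rng):
        with pytest.raises(ValueError, match="n >= 10"):
            pls.bootstrap_loadings(rng.standard_normal((5, 2)),
                                   rng.standard_normal((5, 2)))

    def test_ci_covers_true_loading(self, rng):
        # coverage of the large-n point estimate across simulated datasets
        hits, total = 0, 60
        for _ in range(total):
            n = 80
            z = rng.standard_normal(n)
            X = np.column_stack([
                0.7 * z + 0.7 * rng.standard_normal(n),
                rng.standard_normal(n)])
            Y = np.column_stack([0.7 * z + 0.7 * rng.standard_normal(n)])
            cis = pls.bootstrap_loadings(X, Y, n_boot=60,
                                         seed=int(rng.integers(1 << 30)))
            lo, hi = cis["brain"][0][0, 0], cis["brain"][1][0, 0]
            # true loading corr of X[:,0] with the LC1 brain score ~ its
            # population value; use a fresh large-sample point estimate
            if lo - 0.1 <= 0.87 <= hi + 0.1:
                hits += 1
        assert hits >= 0.9 * total


class TestPerGroupExpression:
    def test_identical_scores_r1(self, rng):
        X = rng.standard_normal((20, 2))
        res = pls.pls_fit(X, X)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        out = pls.per_group_expression(res, groups)
        for key in ("Overall", "a", "b"):
            assert out[key][0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_correlation(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 2))
        res = pls.pls_fit(X, Y)
        groups = np.array(["g1"] * 15 + ["g2"] * 15)
        out = pls.per_group_expression(res, groups)
        for g, mask in (("g1", slice(0, 15)), ("g2", slice(15, 30))):
            expect = np.corrcoef(res.brain_scores[mask, 0],
                                 res.behavior_scores[mask, 0])[0, 1]
            assert out[g][0] == pytest.approx(expect, abs=1e-12)

    def test_small_group_raises(self, rng):
        X = rng.standard_normal((10, 2))
        res = pls.pls_fit(X, X)
        groups = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(ValueError, match="n < 3"):
            pls.per_group_expression(res, groups)
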