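"""Hellinger transform, RDA, permutation inference and forward selection."""

import numpy as np
import pandas as pd
import pytest

from desertniche import (adjusted_r2, forward_select, hellinger,
                         permutation_test, rda_fit, standardize)


def rda_eigen_oracle(Y, X):
    """Brute-force RDA: explicit hat-matrix projection + full eigendecomposition."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    D = np.column_stack([np.ones(n), X])
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    Yh = H @ Yc
    can = np.sort(np.linalg.eigvalsh(Yh.T @ Yh / (n - 1)))[::-1]
    res = np.sort(np.linalg.eigvalsh((Yc - Yh).T @ (Yc - Yh) / (n - 1)))[::-1]
    return can, res


def random_instance(rng, n=None, p=None, m=None):
    n = n or int(rng.integers(10, 25))
    p = p or int(rng.integers(2, 5))
    m = m or int(rng.integers(1, min(4, n - 2)))
    X = rng.normal(size=(n, m))
    Y = rng.normal(size=(n, p))
    return Y, X


class TestHellinger:
    def test_uniform_row(self):
        out = hellinger([[1.0, 1.0, 1.0, 1.0]])
        assert np.allclose(out, 0.5)

    def test_single_occupied_cell(self):
        assert np.allclose(hellinger([[4.0, 0.0, 0.0]]), [[1, 0, 0]])

    def test_rows_have_unit_squared_norm(self, rng):
        Y = rng.gamma(1.0, 1.0, size=(30, 6))
        out = hellinger(Y)
        assert np.allclose((out ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_named_in_error(self):
        Y = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            hellinger(Y)


class TestRdaFit:
    def test_perfect_linear_response(self, rng):
        X = rng.normal(size=(15, 2))
        B = rng.normal(size=(2, 3))
        Y = X @ B + 5.0
        res = rda_fit(Y, X)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.residual_eigenvalues.sum() == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_factor_explains_nothing(self, rng):
        n = 16
        Y = rng.normal(size=(n, 2))
        Yc = Y - Y.mean(axis=0)
        x = rng.normal(size=n)
        x -= x.mean()
        x -= Yc @ np.linalg.lstsq(Yc, x, rcond=None)[0]  # project out Y
        res = rda_fit(Y, x[:, None])
        assert res.r2 == pytest.approx(0.0, abs=1e-10)

    def test_small_instance_matches_brute_force_oracle(self, rng):
        Y = rng.normal(size=(10, 3))
        X = rng.normal(size=(10, 2))
        res = rda_fit(Y, X)
        can, resid = rda_eigen_oracle(Y, X)
        assert np.allclose(res.canonical_eigenvalues,
                           can[: len(res.canonical_eigenvalues)], atol=1e-8)

    def test_many_random_instances_match_oracle(self, rng):
        for _ in range(20):
            Y, X = random_instance(rng)
            res = rda_fit(Y, X)
            can, resid = rda_eigen_oracle(Y, X)
            k = len(res.canonical_eigenvalues)
            assert np.max(np.abs(res.canonical_eigenvalues - can[:k])) < 1e-8

    def test_variance_conservation(self, rng):
        for _ in range(20):
            Y, X = random_instance(rng)
            res = rda_fit(Y, X)
            Yc = Y - Y.mean(axis=0)
            total = (Yc ** 2).sum() / (len(Y) - 1)
            assert res.total_variance == pytest.approx(total, abs=1e-8)
            assert 0.0 <= res.r2 <= 1.0
            assert res.proportion_explained_per_axis.sum() <= 1.0 + 1e-10
            assert 0.0 <= res.cumulative_first_two <= 1.0

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        for _ in range(10):
            Y, X = random_instance(rng)
            res = rda_fit(Y, X)
            assert res.adjusted_r2 <= res.r2 + 1e-12
        assert adjusted_r2(0.5, 20, 0) == pytest.approx(0.5)

    def test_column_order_invariance(self, rng):
        Y, X = random_instance(rng, n=20, p=3, m=3)
        a = rda_fit(Y, X)
        b = rda_fit(Y, X[:, ::-1])
        assert np.allclose(a.canonical_eigenvalues, b.canonical_eigenvalues)
        assert a.r2 == pytest.approx(b.r2)

    def test_rank_deficient_factors_rejected(self, rng):
        Y, X = random_instance(rng, n=15, p=2, m=2)
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="vif_filter"):
            rda_fit(Y, X)

    def test_site_scores_orthogonal(self, rng):
        Y, X = random_instance(rng, n=30, p=4, m=3)
        res = rda_fit(Y, X)
        g = res.site_scores.T @ res.site_scores
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) < 1e-8


class TestPermutationTest:
    def test_determinism_and_addone_rule(self, rng):
        Y, X = random_instance(rng, n=20, p=2, m=2)
        a = permutation_test(Y, X, n_permutations=199, seed=5)
        b = permutation_test(Y, X, n_permutations=199, seed=5)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 200
        assert a.p_value * 200 == pytest.approx(round(a.p_value * 200))

    def test_strong_signal_reaches_floor(self, rng):
        X = rng.normal(size=(50, 2))
        Y = X @ rng.normal(size=(2, 3)) + 0.01 * rng.normal(size=(50, 3))
        res = permutation_test(Y, X, n_permutations=199, seed=3)
        assert res.p_value == pytest.approx(1 / 200)

    def test_minimum_permutations_enforced(self, rng):
        Y, X = random_instance(rng)
        with pytest.raises(ValueError):
            permutation_test(Y, X, n_permutations=10, seed=0)


class TestForwardSelect:
    def test_duplicated_informative_pair_selects_exactly_one(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"x{i}" for i in range(6)])
        X["x_dup"] = X["x0"]
        Y = np.outer(X["x0"], [1.0, 0.7]) + 0.3 * rng.normal(size=(n, 2))
        steps, final = forward_select(Y, X, n_permutations=199, seed=4)
        chosen = {s.factor for s in steps}
        assert len(chosen & {"x0", "x_dup"}) == 1
        assert final is not None

    def test_pure_noise_selects_nothing_or_little(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)),
                         columns=[f"x{i}" for i in range(5)])
        Y = rng.normal(size=(40, 2))
        steps, final = forward_select(Y, X, n_permutations=199, seed=8)
        assert len(steps) <= 1
        if not steps:
            assert final is None

    def test_step_bookkeeping(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=[f"x{i}" for i in range(4)])
        Y = (np.outer(X["x1"], [1.0, 0.5]) + np.outer(X["x3"], [0.5, 1.0])
             + 0.4 * rng.normal(size=(n, 2)))
        steps, final = forward_select(Y, X, n_permutations=199, seed=2)
        assert [s.order for s in steps] == list(range(1, len(steps) + 1))
        assert all(s.p_value <= 0.05 for s in steps)
        assert {s.factor for s in steps} >= {"x1", "x3"}
        total_gain = sum(s.r2_contribution for s in steps)
        assert final.r2 == pytest.approx(total_gain, abs=1e-10)


def test_standardize_zscores(rng):
    X = rng.normal(loc=5.0, scale=3.0, size=(40, 3))
    Z = standardize(X)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        standardize(np.ones((10, 2)))
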