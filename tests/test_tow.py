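"""The optimally weighted interaction score statistic and its permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from towge.tow import (
    TowStatistic,
    optimal_weights,
    permutation_pvalue,
    score_statistic,
    tow_ge_statistic,
)

from conftest import make_residual_set


def _score_oracle(y, S, w):
    """Direct loop evaluation of the exact score statistic."""
    n = len(y)
    s = np.array([sum(w[j] * S[i, j] for j in range(S.shape[1])) for i in range(n)])
    yb, sb = y.mean(), s.mean()
    num = sum((y[i] - yb) * (s[i] - sb) for i in range(n)) ** 2
    den = sum((y[i] - yb) ** 2 for i in range(n)) * sum((s[i] - sb) ** 2 for i in range(n))
    return n * num / den


def _uv_oracle(y, S):
    yb = y.mean()
    U = np.array([sum((y[i] - yb) * (S[i, j] - S[:, j].mean()) for i in range(len(y)))
                  for j in range(S.shape[1])])
    V = np.array([sum((S[i, j] - S[:, j].mean()) ** 2 for i in range(len(y)))
                  for j in range(S.shape[1])])
    return U, V


class TestScoreStatistic:
    def test_matches_hand_oracle(self, rng):
        y = np.array([0.2, -1.1, 0.9, 2.0, -0.5])
        S = np.array([[0.1, 1.2], [0.4, -0.3], [1.5, 0.2], [-0.2, 0.8], [0.9, -1.0]])
        r = make_residual_set(y, S)
        got = score_statistic(r, np.array([1.0, 1.0]))
        assert got == pytest.approx(_score_oracle(y, S, [1.0, 1.0]), abs=1e-10)

    def test_scale_invariance_single_column(self, rng):
        y = rng.standard_normal(8)
        S = rng.standard_normal((8, 1))
        r = make_residual_set(y, S)
        a = score_statistic(r, np.array([1.0]))
        b = score_statistic(r, np.array([-3.7]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_orthogonal_combination_gives_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        S = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        r = make_residual_set(y, S)
        assert score_statistic(r, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_weights_error(self, rng):
        r = make_residual_set(rng.standard_normal(6), rng.standard_normal((6, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            score_statistic(r, np.array([0.0, 0.0]))


class TestOptimalWeights:
    def test_column_equal_to_trait_gets_unit_weight(self, rng):
        y = rng.standard_normal(10)
        r = make_residual_set(y, y.copy())
        wv = optimal_weights(r)
        assert wv.w[0] == pytest.approx(1.0)

    def test_orthogonal_column_gets_zero_weight(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        S = np.column_stack([[1.0, 1.0, -1.0, -1.0], y])
        wv = optimal_weights(make_residual_set(y, S))
        assert wv.w[0] == pytest.approx(0.0, abs=1e-12)
        assert wv.w[1] == pytest.approx(1.0)

    def test_matches_uv_oracle(self, rng):
        y = rng.standard_normal(9)
        S = rng.standard_normal((9, 2))
        wv = optimal_weights(make_residual_set(y, S))
        U, V = _uv_oracle(y, S)
        np.testing.assert_allclose(wv.per_column_score, U, atol=1e-10)
        np.testing.assert_allclose(wv.per_column_ss, V, atol=1e-10)
        np.testing.assert_allclose(wv.w, U / V, atol=1e-10)

    def test_maximizes_diagonal_objective_on_grid(self, rng):
        # brute-force grid over the unit circle of weight directions:
        # the diagonal-approximation objective must peak at w0
        y = rng.standard_normal(12)
        S = rng.standard_normal((12, 2))
        r = make_residual_set(y, S)
        wv = optimal_weights(r)
        yc = y - y.mean()
        U, V = _uv_oracle(y, S)

        def diag_objective(w):
            num = len(y) * (w @ U) ** 2
            den = (yc @ yc) * (w @ (w * V))
            return num / den

        best_grid = max(
            diag_objective(np.array([np.cos(t), np.sin(t)]))
            for t in np.linspace(0, np.pi, 1801)[1:]
        )
        assert diag_objective(wv.w) >= best_grid - 1e-10


class TestTowStatistic:
    def test_equals_sum_of_squared_scores_identity(self, rng):
        y = rng.standard_normal(15)
        S = rng.standard_normal((15, 4))
        r = make_residual_set(y, S)
        U, V = _uv_oracle(y, S)
        assert tow_ge_statistic(r) == pytest.approx(np.sum(U**2 / V), abs=1e-10)

    def test_nonnegative_and_zero_when_orthogonal(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        S = np.column_stack([[1.0, 1.0, -1.0, -1.0], [2.0, 2.0, -2.0, -2.0]])
        assert tow_ge_statistic(make_residual_set(y, S)) == pytest.approx(0.0, abs=1e-12)

    def test_column_rescaling_invariance(self, rng):
        y = rng.standard_normal(10)
        S = rng.standard_normal((10, 3))
        t1 = tow_ge_statistic(make_residual_set(y, S))
        S2 = S.copy()
        S2[:, 1] *= -17.3
        t2 = tow_ge_statistic(make_residual_set(y, S2))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_row_permutation_equivariance(self, rng):
        y = rng.standard_normal(10)
        S = rng.standard_normal((10, 3))
        perm = rng.permutation(10)
        t1 = tow_ge_statistic(make_residual_set(y, S))
        t2 = tow_ge_statistic(make_residual_set(y[perm], S[perm]))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_no_columns_error(self, rng):
        r = make_residual_set(rng.standard_normal(5), np.empty((5, 0)))
        with pytest.raises(ValueError, match="no retained"):
            tow_ge_statistic(r)


class TestPermutationPvalue:
    def test_exhaustive_enumeration_oracle(self, rng):
        # n = 5: all 120 trait permutations enumerable exactly
        y = np.array([0.8, -0.2, 1.4, -1.1, 0.3])
        S = np.array([[0.5, -0.1], [1.2, 0.7], [-0.3, 0.2], [0.1, -1.4], [0.9, 0.6]])
        r = make_residual_set(y, S)
        t_obs = tow_ge_statistic(r)
        exact_ge = np.mean(
            [
                tow_ge_statistic(make_residual_set(np.array(p), S)) >= t_obs - 1e-12
                for p in itertools.permutations(y)
            ]
        )
        B = 4000
        res = permutation_pvalue(r, B=B, seed=11)
        expected = (1 + B * exact_ge) / (B + 1)
        mc_se = np.sqrt(exact_ge * (1 - exact_ge) / B)
        assert abs(res.p_value - expected) <= 3 * mc_se

    def test_add_one_floor_when_observed_is_maximal(self):
        # trait identical to the single column: by Cauchy-Schwarz no
        # permutation can beat the observed score
        y = np.array([3.0, -2.0, 1.0, 0.5, -1.5, 2.5, -0.7, 0.9])
        r = make_residual_set(y, y.copy())
        res = permutation_pvalue(r, B=60, seed=2)
        assert res.p_value == pytest.approx(1 / 61)

    def test_constant_statistic_returns_one(self):
        r = make_residual_set(np.zeros(6), np.arange(6.0))
        with pytest.warns(UserWarning, match="constant"):
            res = permutation_pvalue(r, B=20, seed=0)
        assert res.p_value == 1.0

    def test_raw_convention_matches_paper_formula(self, rng):
        y = rng.standard_normal(12)
        S = rng.standard_normal((12, 2))
        r = make_residual_set(y, S)
        res = permutation_pvalue(r, B=200, seed=5, convention="raw")
        # recompute from the same stream
        stat = TowStatistic(S - S.mean(axis=0))
        rng2 = np.random.default_rng(5)
        from towge.tow import permuted_rows

        yc = y - y.mean()
        t_perm = stat.batch(permuted_rows(yc, 200, rng2))
        assert res.p_value == pytest.approx(np.sum(t_perm > stat.observed(yc)) / 200)

    def test_permute_raw_agrees_with_residual_shuffle(self, rng):
        # the two permutation targets define the same null; p-values agree
        # within Monte-Carlo error
        n = 30
        design = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        from towge.residualize import _lstsq_residuals

        y_res = _lstsq_residuals(design, y[:, None]).ravel()
        S_res = _lstsq_residuals(design, rng.standard_normal((n, 3)))
        r = make_residual_set(y_res, S_res, design=design)
        r.y_raw = y
        B = 1500
        p1 = permutation_pvalue(r, B=B, seed=3).p_value
        p2 = permutation_pvalue(r, B=B, seed=3, permute_raw=True).p_value
        se = np.sqrt(max(p1, 1 / B) * (1 - min(p1, 1 - 1 / B)) / B)
        assert abs(p1 - p2) <= 4 * se + 2 / B

    def test_null_pvalues_uniform(self, rng):
        # fixed interaction columns, independent standard-normal trait:
        # permutation p-values are (discretely) uniform
        n, B, reps = 25, 200, 500
        S = rng.standard_normal((n, 3))
        pvals = np.empty(reps)
        for i in range(reps):
            r = make_residual_set(rng.standard_normal(n), S)
            pvals[i] = permutation_pvalue(r, B=B, seed=int(rng.integers(2**31))).p_value
        # randomized PIT removes the add-one grid's discreteness
        smooth = pvals - rng.uniform(0, 1 / (B + 1), size=reps)
        assert stats.kstest(smooth, "uniform").pvalue > 0.01
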