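"""Unit and property tests for the 2dGBH core: pi0 estimators, shrinkage,
balance factor, per-cell combination, weighting and the BH step-up."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdgbh import (
    CombineMode,
    PValueMatrix,
    Pi0Config,
    bh_adjust,
    combine_pi0,
    compute_balance_factor,
    compute_weights,
    estimate_pi0_lsl,
    estimate_pi0_storey,
    estimate_pi0_tst,
    shrink_group_pi0,
    two_d_gbh,
    weight_pvalues,
)
from conftest import brute_force_bh_rejections

pvec = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50
).map(np.array)


class TestStorey:
    @pytest.mark.parametrize(
        "p, lam, expected",
        [
            ([0.1, 0.2, 0.6, 0.8], 0.5, 1.0),  # 2 / (0.5 * 4), clipped at 1
            ([1.0] * 7, 0.3, 1.0),  # raw estimate > 1 is clipped
            ([0.9, 0.95], 0.5, 1.0),
            ([0.1, 0.2, 0.3, 0.8], 0.5, 0.5),  # 1 / (0.5 * 4)
        ],
    )
    def test_tail_count(self, p, lam, expected):
        assert estimate_pi0_storey(p, lam) == pytest.approx(expected)

    def test_uniform_null_approaches_one(self, rng):
        ests = [
            estimate_pi0_storey(rng.uniform(size=10000), 0.5) for _ in range(20)
        ]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.02)

    def test_floor_clipping(self):
        assert estimate_pi0_storey([0.0, 0.1], 0.5, pi0_floor=1e-8) == 1e-8

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_pi0_storey([])
        with pytest.raises(ValueError):
            estimate_pi0_storey([0.5], lam=1.0)


class TestLsl:
    def test_saturated_null(self):
        assert estimate_pi0_lsl([1.0] * 6) == 1.0

    def test_signal_mixture_below_one(self):
        p = [0.001, 0.002, 0.003, 0.5, 0.6, 0.7, 0.8, 0.9]
        # hand oracle: slopes (1 - p_(i)) / (9 - i) rise to l_3 = 0.997 / 6
        # and first decrease at i = 4; pi0 = (1 / l_3 + 1) / 8
        expected = (6.0 / 0.997 + 1.0) / 8.0
        est = estimate_pi0_lsl(p)
        assert est == pytest.approx(expected)
        assert est < 1.0

    def test_uniform_null_approaches_one(self, rng):
        ests = [estimate_pi0_lsl(rng.uniform(size=10000)) for _ in range(10)]
        assert np.mean(ests) == pytest.approx(1.0, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_pi0_lsl([])


class TestTst:
    def test_saturated_null(self):
        assert estimate_pi0_tst([1.0] * 8, alpha=0.05) == 1.0

    def test_two_block_mixture(self):
        p = np.array([1e-10] * 5 + [0.9] * 5)
        # brute-force step-up at level 0.05 / 1.05 rejects exactly the 5
        # tiny p-values, so pi0 = (10 - 5) / 10
        stage = 0.05 / 1.05
        assert brute_force_bh_rejections(p, stage).sum() == 5
        assert estimate_pi0_tst(p, alpha=0.05) == pytest.approx(0.5)

    def test_single_pvalue(self):
        assert estimate_pi0_tst([0.5], alpha=0.05) == 1.0


class TestShrink:
    def test_hand_example(self):
        assert shrink_group_pi0([0.5], 0.9, 0.1)[0] == pytest.approx(0.54)

    @given(
        raw=st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=20,
        ),
        glob=st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_limits_and_range(self, raw, glob):
        raw = np.array(raw)
        assert np.allclose(shrink_group_pi0(raw, glob, 0.0), raw)
        assert np.allclose(shrink_group_pi0(raw, glob, 1.0), glob)
        mid = shrink_group_pi0(raw, glob, 0.3)
        assert np.all(mid >= np.minimum(raw, glob) - 1e-12)
        assert np.all(mid <= np.maximum(raw, glob) + 1e-12)


class TestBalanceFactor:
    def test_zero_column_spread_gives_row_only(self):
        assert compute_balance_factor(0.3, 0.0, 100, 10) == 0.0

    def test_symmetry(self):
        assert compute_balance_factor(0.2, 0.2, 50, 50) == pytest.approx(0.5)

    def test_hand_example(self):
        R = compute_balance_factor(0.1, 0.2, 1000, 20)
        assert R == pytest.approx(0.01 / 0.0101)

    def test_degenerate_returns_half(self):
        assert compute_balance_factor(0.0, 0.0, 10, 10) == 0.5


class TestCombine:
    def test_one_direction_limits(self):
        row = np.array([0.3, 0.6, 0.9])
        col = np.array([0.5, 1.0])
        cell0 = combine_pi0(row, col, R=0.0)
        assert np.allclose(cell0, np.tile(row[:, None], (1, 2)))
        cell1 = combine_pi0(row, col, R=1.0)
        assert np.allclose(cell1, np.tile(col[None, :], (3, 1)))

    def test_weighted_hand_example(self):
        cell = combine_pi0([0.4], [0.9], R=0.5, mode=CombineMode.WEIGHTED)
        assert cell[0, 0] == pytest.approx(0.6)

    def test_geometric_ignores_R(self):
        a = combine_pi0([0.4], [0.9], R=0.9, mode=CombineMode.GEOMETRIC)
        b = combine_pi0([0.4], [0.9], R=0.1, mode=CombineMode.GEOMETRIC)
        assert a[0, 0] == b[0, 0] == pytest.approx(0.6)

    def test_arithmetic(self):
        cell = combine_pi0([0.4], [0.9], R=0.5, mode=CombineMode.ARITHMETIC)
        assert cell[0, 0] == pytest.approx(0.65)


class TestWeights:
    @pytest.mark.parametrize("pi0, w", [(0.5, 1.0), (1.0, 0.0), (0.2, 4.0)])
    def test_values(self, pi0, w):
        assert compute_weights(np.array([[pi0]])).W[0, 0] == pytest.approx(w)

    def test_rejects_zero_pi0(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([[0.0]]))


class TestWeightPvalues:
    def test_uniform_halving(self, rng):
        P = rng.uniform(size=(4, 3))
        W = np.ones((4, 3))
        assert np.allclose(weight_pvalues(P, W, 0.5), P * 0.5)

    def test_zero_weight_is_never_rejectable(self):
        P = np.array([[1e-12, 0.5], [0.5, 0.5]])
        W = np.array([[0.0, 1.0], [1.0, 1.0]])
        pw = weight_pvalues(P, W, 0.9)
        assert np.isinf(pw[0, 0])
        adjusted = bh_adjust(pw)
        assert adjusted[0, 0] == 1.0


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
            ([0.02, 0.9], [0.04, 0.9]),
        ],
    )
    def test_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_preserves_shape_and_order(self, rng):
        p = rng.uniform(size=(6, 4))
        adj = bh_adjust(p)
        assert adj.shape == p.shape
        # adjustment is monotone: ordering by raw p never decreases adjusted
        order = np.argsort(p.ravel())
        assert np.all(np.diff(adj.ravel()[order]) >= -1e-15)

    @given(p=pvec)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_step_up_oracle(self, p):
        adj = bh_adjust(p)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5, 0.9):
            assert np.array_equal(adj <= alpha, brute_force_bh_rejections(p, alpha))


class TestTwoDGbh:
    def test_saturated_null_rejects_nothing(self):
        result = two_d_gbh(np.ones((10, 5)), alpha=0.5)
        assert result.n_rejected == 0

    def test_full_shrinkage_reduces_to_bh_at_scaled_level(self, rng):
        # with S = 1 every cell pi0 collapses to the global estimate g and
        # the weighted p-values become p * g: BH at alpha equals BH on the
        # raw p-values at level alpha / g (for g < 1; when g clips to 1 all
        # weights vanish and nothing is rejected)
        n_identity = 0
        for _ in range(10):
            p = rng.uniform(size=(40, 6))
            p[:4, :2] *= 1e-3
            result, surface = two_d_gbh(
                p, Pi0Config(shrinkage=1.0), alpha=0.05, return_surface=True
            )
            g = surface.pi0_global
            assert np.allclose(surface.pi0_cell, g)
            if g < 1.0:
                expected = brute_force_bh_rejections(p, 0.05 / g)
                n_identity += 1
            else:
                expected = np.zeros_like(result.rejected)
            assert np.array_equal(result.rejected, expected)
        assert n_identity >= 3

    def test_forced_balance_uses_single_direction(self, signal_matrix):
        for override, attr in ((0.0, "pi0_row_shrunk"), (1.0, "pi0_col_shrunk")):
            _, surface = two_d_gbh(
                signal_matrix,
                Pi0Config(balance_override=override),
                return_surface=True,
            )
            vec = getattr(surface, attr)
            expected = (
                np.tile(vec[:, None], (1, signal_matrix.n_outcomes))
                if override == 0.0
                else np.tile(vec[None, :], (signal_matrix.n_features, 1))
            )
            assert np.array_equal(surface.pi0_cell, np.clip(expected, 1e-8, 1.0))

    def test_monotone_in_alpha(self, signal_matrix):
        r1 = two_d_gbh(signal_matrix, alpha=0.01).rejected
        r2 = two_d_gbh(signal_matrix, alpha=0.10).rejected
        assert np.all(r2[r1])  # rejections at 1% are kept at 10%

    def test_permutation_equivariance(self, signal_matrix, rng):
        perm_r = rng.permutation(signal_matrix.n_features)
        perm_c = rng.permutation(signal_matrix.n_outcomes)
        base = two_d_gbh(signal_matrix)
        permuted = two_d_gbh(signal_matrix.values[np.ix_(perm_r, perm_c)])
        assert np.array_equal(
            base.p_adjusted[np.ix_(perm_r, perm_c)], permuted.p_adjusted
        )
        assert base.n_rejected == permuted.n_rejected

    def test_deterministic(self, signal_matrix):
        a = two_d_gbh(signal_matrix)
        b = two_d_gbh(signal_matrix)
        assert np.array_equal(a.p_adjusted, b.p_adjusted)

    def test_surface_invariants(self, signal_matrix):
        cfg = Pi0Config()
        _, s = two_d_gbh(signal_matrix, cfg, return_surface=True)
        S = cfg.shrinkage
        assert np.allclose(
            s.pi0_row_shrunk, (1 - S) * s.pi0_row_raw + S * s.pi0_global
        )
        assert np.allclose(
            s.pi0_col_shrunk, (1 - S) * s.pi0_col_raw + S * s.pi0_global
        )
        assert s.pi0_w == pytest.approx(s.pi0_cell.mean())
        assert 0.0 <= s.R <= 1.0
        for arr in (s.pi0_row_raw, s.pi0_col_raw, s.pi0_cell):
            assert np.all((arr > 0) & (arr <= 1))

    def test_rejection_mask_matches_adjusted(self, signal_matrix):
        res = two_d_gbh(signal_matrix, alpha=0.07)
        assert np.array_equal(res.rejected, res.p_adjusted <= 0.07)


class TestPValueMatrixValidation:
    def test_rejects_nan(self):
        bad = np.full((3, 3), 0.5)
        bad[1, 2] = np.nan
        with pytest.raises(ValueError, match="row 1, column 2"):
            PValueMatrix(bad)

    def test_rejects_out_of_range(self):
        bad = np.full((3, 3), 0.5)
        bad[0, 0] = 1.5
        with pytest.raises(ValueError, match="outside"):
            PValueMatrix(bad)

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            PValueMatrix(np.full((1, 5), 0.5))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            PValueMatrix(np.full((2, 2), 0.5), feature_ids=["a", "a"])
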