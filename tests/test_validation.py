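import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_grid
from wuimap.grid import Raster, RasterKind
from wuimap.validation import (
    WUI_BINARY_MAPPING,
    ValidationDesign,
    allocate_equal,
    area_adjusted_accuracy,
    collapse_classes,
    draw_stratified_sample,
    sample_size,
)


class TestSampleSize:
    def test_uniform_075_s001_is_1875(self):
        assert sample_size([0.2] * 5, [0.75] * 5, 0.01) == 1875

    def test_uniform_075_s002_is_469(self):
        assert sample_size([0.2] * 5, [0.75] * 5, 0.02) == 469  # ceil(468.75)

    def test_mixed_targets(self):
        assert sample_size([0.9, 0.1], [0.9, 0.7], 0.01) == 998

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_invariant_to_w_when_u_uniform(self, raw):
        W = np.asarray(raw) / np.sum(raw)
        assert sample_size(W, np.full(W.size, 0.75), 0.01) == 1875

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            sample_size([1.0], [0.75], 0.0)
        with pytest.raises(ValueError):
            sample_size([1.0], [1.0], 0.01)
        with pytest.raises(ValueError, match="sum to 1"):
            sample_size([0.5, 0.4], [0.75, 0.75], 0.01)


class TestAllocation:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (1504, 5, [301, 301, 301, 301, 300]),
            (10, 5, [2, 2, 2, 2, 2]),
            (7, 3, [3, 2, 2]),
        ],
    )
    def test_equal_allocation(self, n, k, expected):
        assert allocate_equal(n, k).tolist() == expected

    @given(st.integers(1, 12), st.integers(0, 500))
    def test_sums_and_balance(self, k, extra):
        n = k + extra
        alloc = allocate_equal(n, k)
        assert alloc.sum() == n
        assert alloc.max() - alloc.min() <= 1

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            allocate_equal(3, 5)

    def test_design_uses_formula_or_override(self):
        d = ValidationDesign.build([0.2] * 5, [0.75] * 5, 0.01)
        assert d.n == 1875
        d2 = ValidationDesign.build([0.2] * 5, [0.75] * 5, 0.01, n=1504)
        assert d2.n == 1504 and d2.allocation.tolist() == [301, 301, 301, 301, 300]


class TestStratifiedSample:
    def _raster(self):
        g = make_grid(n_rows=20, n_cols=20)
        codes = np.zeros(g.shape, np.uint8)
        codes[:, 10:] = 1
        return Raster(g, codes, RasterKind.CATEGORICAL)

    def test_counts_per_stratum(self):
        sample = draw_stratified_sample(self._raster(), np.array([2, 2]), seed=1)
        assert len(sample) == 4
        assert (sample["map_class"] == 0).sum() == 2
        assert (sample["map_class"] == 1).sum() == 2

    def test_reproducible_under_seed(self):
        a = draw_stratified_sample(self._raster(), np.array([5, 5]), seed=42)
        b = draw_stratified_sample(self._raster(), np.array([5, 5]), seed=42)
        assert a.equals(b)
        c = draw_stratified_sample(self._raster(), np.array([5, 5]), seed=43)
        assert not a.equals(c)

    def test_sample_points_lie_in_their_stratum(self):
        r = self._raster()
        sample = draw_stratified_sample(r, np.array([30, 30]), seed=0)
        for _, row in sample.iterrows():
            assert r.values[int(row["row"]), int(row["col"])] == row["map_class"]
        assert not sample.duplicated(["row", "col"]).any()  # without replacement

    def test_undersized_stratum_named_in_error(self):
        g = make_grid(n_rows=2, n_cols=2)
        codes = np.array([[0, 0], [0, 1]], np.uint8)
        with pytest.raises(ValueError, match="stratum 1"):
            draw_stratified_sample(Raster(g, codes, RasterKind.CATEGORICAL),
                                   np.array([1, 2]), seed=0)


class TestAreaAdjustedAccuracy:
    def test_perfect_map(self):
        est = area_adjusted_accuracy(np.eye(3) * 20, [0.5, 0.3, 0.2])
        assert est.overall == 1.0
        np.testing.assert_allclose(est.users, 1.0)
        np.testing.assert_allclose(est.producers, 1.0)

    def test_two_class_worked_example(self):
        counts = np.array([[45, 5], [10, 40]])
        est = area_adjusted_accuracy(counts, [0.9, 0.1])
        assert est.overall == pytest.approx(0.89, abs=1e-12)
        assert est.naive_overall == pytest.approx(0.85, abs=1e-12)
        assert est.users[0] == pytest.approx(0.9, abs=1e-12)
        assert est.producers[0] == pytest.approx(0.81 / 0.83, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_w_proportional_to_rows_equals_naive(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, size=(4, 4)).astype(float)
        W = counts.sum(axis=1) / counts.sum()
        est = area_adjusted_accuracy(counts, W)
        assert est.overall == pytest.approx(est.naive_overall, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_cell_proportions_sum_to_one(self, seed):
        rng = np.random.default_rng(10 + seed)
        counts = rng.integers(1, 30, size=(5, 5))
        W = rng.dirichlet(np.ones(5))
        est = area_adjusted_accuracy(counts, W)
        assert abs(est.p.sum() - 1.0) <= 1e-12

    def test_zero_row_with_positive_weight_rejected(self):
        counts = np.array([[10, 0], [0, 0]])
        with pytest.raises(ValueError, match="no samples"):
            area_adjusted_accuracy(counts, [0.5, 0.5])

    def test_monte_carlo_calibration_recovers_true_oa(self):
        # simulate reference labels from a known confusion model at n = 1500
        rng = np.random.default_rng(2024)
        k = 5
        W = np.array([0.9, 0.04, 0.03, 0.02, 0.01])
        # true per-map-class reference distribution: 80% correct, rest uniform
        P_ref = np.full((k, k), 0.05)
        np.fill_diagonal(P_ref, 0.8)
        true_oa = float((W * 0.8).sum())
        alloc = allocate_equal(1500, k)
        counts = np.vstack([rng.multinomial(n, P_ref[i]) for i, n in enumerate(alloc)])
        est = area_adjusted_accuracy(counts, W)
        # SE of stratified OA estimator
        ua = counts.diagonal() / counts.sum(axis=1)
        se = float(np.sqrt(np.sum(W**2 * ua * (1 - ua) / (counts.sum(axis=1) - 1))))
        assert abs(est.overall - true_oa) <= 3 * se


class TestCollapse:
    def test_identity_collapses_to_identity(self):
        counts, W = collapse_classes(np.eye(5) * 10, [0.2] * 5, WUI_BINARY_MAPPING)
        np.testing.assert_allclose(counts, np.diag([10, 40]))
        np.testing.assert_allclose(W, [0.2, 0.8])

    @pytest.mark.parametrize("seed", range(5))
    def test_within_group_confusion_vanishes_after_collapse(self, seed):
        rng = np.random.default_rng(seed)
        # confusion only among WUI classes: binary OA must reach 1
        counts = np.zeros((5, 5))
        counts[0, 0] = 50
        counts[1:, 1:] = rng.integers(1, 20, size=(4, 4))
        W = rng.dirichlet(np.ones(5))
        c2, w2 = collapse_classes(counts, W, WUI_BINARY_MAPPING)
        est5 = area_adjusted_accuracy(counts, W)
        est2 = area_adjusted_accuracy(c2, w2)
        assert est2.overall == pytest.approx(1.0)
        assert est2.overall >= est5.overall

    def test_collapse_all_to_one_gives_perfect_accuracy(self):
        counts = np.arange(1, 10).reshape(3, 3)
        c1, w1 = collapse_classes(counts, [0.3, 0.3, 0.4], np.zeros(3, int))
        assert area_adjusted_accuracy(c1, w1).overall == 1.0

    def test_non_surjective_mapping_rejected(self):
        with pytest.raises(ValueError, match="surjection"):
            collapse_classes(np.eye(3), [0.3, 0.3, 0.4], np.array([0, 2, 2]))
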