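"""DTW kernel against enumeration oracles; hypermatrix machinery; clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flocknet.dtw import (
    build_hypermatrix,
    cluster_hens,
    collapse_hypermatrix,
    daily_dissimilarity_trend,
    daily_distance_matrices,
    diana_labels,
    dtw_distance,
    dtw_distance_reference,
    summed_matrix_from_daily,
    within_between_comparison,
)


def enumerate_paths_cost(x, y):
    """Literal exhaustive enumeration of every monotone warping path.

    Feasible only for short series; the ground truth the DP must match.
    """
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(x[i] - y[j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], cost)
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwDistance:
    @pytest.mark.parametrize(
        "x, y, want",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1], [4], 3.0),
            ([1, 1, 2, 2], [1, 2, 2, 2], 0.0),
            ([1, 3], [2], 2.0),
        ],
    )
    def test_known_values(self, x, y, want):
        assert dtw_distance(x, y) == want

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1, 2])

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(100):
            nx_, ny = rng.integers(1, 7, size=2)
            x = rng.integers(1, 5, size=nx_).astype(float)
            y = rng.integers(1, 5, size=ny).astype(float)
            assert dtw_distance(x, y) == enumerate_paths_cost(x, y)

    def test_matches_reference_recursion(self, rng):
        for _ in range(200):
            nx_, ny = rng.integers(1, 13, size=2)
            x = rng.integers(1, 5, size=nx_).astype(float)
            y = rng.integers(1, 5, size=ny).astype(float)
            assert dtw_distance(x, y) == dtw_distance_reference(x, y)

    def test_metric_style_properties(self, rng):
        for _ in range(50):
            x = rng.integers(1, 5, size=rng.integers(2, 30)).astype(float)
            y = rng.integers(1, 5, size=rng.integers(2, 30)).astype(float)
            assert dtw_distance(x, x) == 0.0
            assert dtw_distance(x, y) == dtw_distance(y, x)
            assert dtw_distance(x, y) >= 0.0

    def test_joint_whole_bin_shift_invariance(self, rng):
        """Delaying both hens' transitions by the same number of bins is free."""
        for _ in range(50):
            L = 40
            x, y = np.ones(L), np.ones(L)
            for s in (x, y):
                t = 5
                while t < L - 12:
                    run, lev = rng.integers(2, 6), rng.integers(2, 5)
                    s[t : t + run] = lev
                    t += run + rng.integers(1, 5)
            k = int(rng.integers(1, 5))
            xs = np.concatenate([np.ones(k), x[:-k]])
            ys = np.concatenate([np.ones(k), y[:-k]])
            assert dtw_distance(xs, ys) == dtw_distance(x, y)

    def test_normalized_variant_divides_by_path_length(self):
        assert dtw_distance([1, 4], [1, 4], normalize=True) == 0.0
        assert dtw_distance([1], [4], normalize=True) == 3.0


class TestHypermatrix:
    def test_two_hens_one_day(self, rng):
        series = rng.integers(1, 5, size=(2, 1, 20)).astype(np.int8)
        M4 = build_hypermatrix(series)
        assert M4.shape == (2, 1, 2, 1)
        assert M4[0, 0, 1, 0] == dtw_distance(series[0, 0], series[1, 0])
        assert M4[0, 0, 0, 0] == 0.0

    def test_identical_series_all_zero(self):
        series = np.full((3, 2, 15), 2, dtype=np.int8)
        assert (build_hypermatrix(series) == 0).all()

    def test_entries_match_direct_calls_and_symmetry(self, rng):
        series = rng.integers(1, 5, size=(3, 2, 12)).astype(np.int8)
        M4 = build_hypermatrix(series)
        for (i, j), (k, l) in itertools.combinations(
            itertools.product(range(3), range(2)), 2
        ):
            d = dtw_distance(series[i, j], series[k, l])
            assert M4[i, j, k, l] == d == M4[k, l, i, j]

    def test_daily_matrices_agree_with_hypermatrix(self, rng):
        series = rng.integers(1, 5, size=(4, 3, 10)).astype(np.int8)
        M4 = build_hypermatrix(series)
        daily = daily_distance_matrices(series)
        for d in range(3):
            assert np.array_equal(daily[d], M4[:, d, :, d])


class TestCollapse:
    def test_unit_distances_sum_to_day_count(self):
        a, b = 4, 10
        M4 = np.ones((a, b, a, b))
        for i in range(a):
            for j in range(b):
                M4[i, j, i, j] = 0
        A = collapse_hypermatrix(M4)
        off = A[~np.eye(a, dtype=bool)]
        assert (off == b).all()

    def test_single_day_equals_distance_matrix(self, rng):
        series = rng.integers(1, 5, size=(3, 1, 10)).astype(np.int8)
        M4 = build_hypermatrix(series)
        assert np.array_equal(collapse_hypermatrix(M4), M4[:, 0, :, 0])

    def test_matches_double_loop_oracle(self, rng):
        a, b = 3, 4
        M4 = rng.random((a, b, a, b))
        M4 = (M4 + M4.transpose(2, 3, 0, 1)) / 2
        want = np.zeros((a, a))
        for i in range(a):
            for k in range(a):
                if i != k:
                    for d in range(b):
                        want[i, k] += M4[i, d, k, d]
        got = collapse_hypermatrix(M4)
        np.fill_diagonal(want, 0)
        assert np.allclose(got, want)
        daily = np.stack([M4[:, d, :, d] for d in range(b)])
        off = ~np.eye(a, dtype=bool)
        assert np.allclose(summed_matrix_from_daily(daily)[off], got[off])


class TestWithinBetween:
    def test_within_always_smaller_gives_V_zero(self):
        # three hens, each internally consistent, mutually very different
        base = np.array([[1] * 10, [2] * 10, [4] * 10], dtype=np.int8)
        series = np.stack([np.stack([b, b]) for b in base])  # (3, 2, 10)
        M4 = build_hypermatrix(series)
        res = within_between_comparison(M4)
        assert (res.per_hen.median_within < res.per_hen.median_between).all()
        assert res.V == 0.0 and res.p < 0.2  # n=3 limits attainable p

    def test_identical_hens_degenerate(self):
        series = np.full((3, 2, 10), 2, dtype=np.int8)
        res = within_between_comparison(build_hypermatrix(series))
        assert res.degenerate

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            within_between_comparison(np.zeros((3, 1, 3, 1)))


class TestClustering:
    def test_two_blocks_exact_recovery(self):
        A = np.full((6, 6), 10.0)
        A[:3, :3] = 0.0
        A[3:, 3:] = 0.0
        np.fill_diagonal(A, 0.0)
        for method in ("diana", "complete"):
            res = cluster_hens(A, k=2, method=method)
            labs = [res.labels[i] for i in range(6)]
            assert labs[:3] == [labs[0]] * 3 and labs[3:] == [labs[3]] * 3
            assert labs[0] != labs[3]

    def test_silhouette_selects_planted_k(self):
        rng = np.random.default_rng(0)
        A = np.full((12, 12), 10.0) + rng.random((12, 12))
        A = (A + A.T) / 2
        for blk in (slice(0, 4), slice(4, 8), slice(8, 12)):
            A[blk, blk] = rng.random((4, 4)) * 0.5
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        res = cluster_hens(A)  # k chosen by silhouette
        assert res.k == 3

    def test_all_equal_distances_split_contiguously(self):
        A = np.ones((5, 5)) - np.eye(5)
        res = cluster_hens(A, k=3, method="diana")
        # deterministic tie-break: lowest-index singletons split off first
        assert res.labels == {0: 1, 1: 2, 2: 3, 3: 3, 4: 3}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_hens(np.zeros((3, 3)), k=5)

    def test_diana_deterministic(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        assert np.array_equal(diana_labels(A, 4), diana_labels(A, 4))


class TestDailyTrend:
    def test_constant_daily_means_flat(self):
        daily = np.ones((6, 4, 4))
        for d in range(6):
            np.fill_diagonal(daily[d], 0)
        fit = daily_dissimilarity_trend(daily)
        assert fit.slope == pytest.approx(0.0)
        assert fit.F == pytest.approx(0.0, abs=1e-9)

    def test_linear_daily_means_perfect_fit(self):
        daily = np.stack([np.full((3, 3), 1.0 + 0.5 * d) for d in range(8)])
        for d in range(8):
            np.fill_diagonal(daily[d], 0)
        fit = daily_dissimilarity_trend(daily)
        assert fit.slope == pytest.approx(0.5)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            daily_dissimilarity_trend(np.zeros((2, 3, 3)))
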