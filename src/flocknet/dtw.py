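"""Dynamic time warping of daily area-occupancy series.

Classic DTW with local cost |u - v|, the symmetric step pattern
(match / insert / delete, no slope weights) and no global window; the
returned value is the raw cumulative cost of the optimal warping path
(no normalization -- a dimensionless dissimilarity).  A pure-Python
memoized reference implementation is kept alongside the numba kernel as
an independent check.

On top of the pairwise distance the module builds the a x b x a x b
dissimilarity hypermatrix over all hen-day series, the within/between
hen consistency contrast, the summed (same-day) dyadic distance matrix,
divisive (Diana) and agglomerative clustering of hens, and the linear
trend of daily mean dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "dtw_distance",
    "dtw_distance_reference",
    "build_hypermatrix",
    "daily_distance_matrices",
    "collapse_hypermatrix",
    "summed_matrix_from_daily",
    "within_between_comparison",
    "WithinBetweenResult",
    "ClusterAssignment",
    "cluster_hens",
    "diana_labels",
    "daily_dissimilarity_trend",
    "TrendFit",
]


@njit(cache=True)
def _dtw_kernel(x, y):  # pragma: no cover - exercised via dtw_distance
    n, m = len(x), len(y)
    prev = np.empty(m, dtype=np.float64)
    curr = np.empty(m, dtype=np.float64)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        curr[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, m):
            c = abs(x[i] - y[j])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[m - 1]


def dtw_distance(x, y, normalize: bool = False) -> float:
    """DTW dissimilarity between two series (cumulative |u-v| path cost).

    ``normalize=True`` divides by the optimal path length; useful when
    comparing windows of unequal length, off by default.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("series must be non-empty")
    d = float(_dtw_kernel(x, y))
    if normalize:
        d /= _path_length(x, y)
    return d


def _path_length(x, y) -> int:
    # length of an optimal warping path under the same step pattern
    n, m = len(x), len(y)
    D = np.full((n, m), np.inf)
    Lp = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            c = abs(x[i] - y[j])
            if i == 0 and j == 0:
                D[i, j], Lp[i, j] = c, 1
                continue
            cands = []
            if i > 0:
                cands.append((D[i - 1, j], Lp[i - 1, j]))
            if j > 0:
                cands.append((D[i, j - 1], Lp[i, j - 1]))
            if i > 0 and j > 0:
                cands.append((D[i - 1, j - 1], Lp[i - 1, j - 1]))
            best = min(cands)
            D[i, j], Lp[i, j] = c + best[0], best[1] + 1
    return int(Lp[n - 1, m - 1])


def dtw_distance_reference(x, y) -> float:
    """Slow top-down reference DTW (memoized recursion over all moves).

    Independent of the bottom-up numba kernel; used as an oracle in the
    test suite and for spot checks.
    """
    xs = tuple(float(v) for v in x)
    ys = tuple(float(v) for v in y)
    if not xs or not ys:
        raise ValueError("series must be non-empty")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        c = abs(xs[i] - ys[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, (len(xs) + 1) * (len(ys) + 1) + 100))
    try:
        return rec(len(xs) - 1, len(ys) - 1)
    finally:
        sys.setrecursionlimit(old)


@njit(cache=True)
def _pairwise_kernel(flat, out):  # pragma: no cover
    N = flat.shape[0]
    for p in range(N):
        for q in range(p + 1, N):
            d = _dtw_kernel(flat[p], flat[q])
            out[p, q] = d
            out[q, p] = d


def build_hypermatrix(series: np.ndarray) -> np.ndarray:
    """All-pairs DTW distances over hen-day series.

    Parameters
    ----------
    series : (a, b, L) array of area codes, one row per hen-day.

    Returns the (a, b, a, b) hypermatrix ``dd`` with
    ``dd[i, j, k, l] = dtw(series[i, j], series[k, l])``; symmetric under
    (i, j) <-> (k, l), zero on the hen-day diagonal.
    """
    series = np.asarray(series)
    if series.ndim != 3:
        raise ValueError("series must be (hens, days, samples)")
    if np.isnan(series.astype(np.float64)).any():
        raise ValueError("missing hen-day series; impute or drop the day first")
    a, b, L = series.shape
    flat = np.ascontiguousarray(series.reshape(a * b, L).astype(np.float64))
    out = np.zeros((a * b, a * b), dtype=np.float64)
    _pairwise_kernel(flat, out)
    return out.reshape(a, b, a, b)


@njit(cache=True)
def _daily_kernel(series, out):  # pragma: no cover
    b, a = series.shape[0], series.shape[1]
    for d in range(b):
        for i in range(a):
            for k in range(i + 1, a):
                v = _dtw_kernel(series[d, i], series[d, k])
                out[d, i, k] = v
                out[d, k, i] = v


def daily_distance_matrices(series: np.ndarray) -> np.ndarray:
    """Same-day cross-hen DTW distances: (b, a, a) stack of daily matrices."""
    series = np.asarray(series)
    a, b, L = series.shape
    byday = np.ascontiguousarray(series.transpose(1, 0, 2).astype(np.float64))
    out = np.zeros((b, a, a), dtype=np.float64)
    _daily_kernel(byday, out)
    return out


def collapse_hypermatrix(M4: np.ndarray) -> np.ndarray:
    """Summed dyadic matrix A[i, k] = sum over days d of dd[i, d, k, d]."""
    a, b = M4.shape[0], M4.shape[1]
    A = np.zeros((a, a))
    for d in range(b):
        A += M4[:, d, :, d]
    np.fill_diagonal(A, 0.0)
    return A


def summed_matrix_from_daily(daily: np.ndarray) -> np.ndarray:
    """Summed dyadic matrix from the (b, a, a) daily stack."""
    return daily.sum(axis=0)


@dataclass
class WithinBetweenResult:
    per_hen: pd.DataFrame  # hen index, median_within, median_between
    V: float
    p: float
    degenerate: bool = False


def within_between_comparison(M4: np.ndarray, hens: list[str] | None = None) -> WithinBetweenResult:
    """Within-hen vs between-hen daily-series dissimilarity contrast.

    For each hen: the median DTW distance over its own b(b-1)/2 day
    pairs (within) and over all cross-hen hen-day pairs involving it
    (between).  A paired one-sided Wilcoxon signed-rank test asks
    whether within-hen medians are systematically smaller -- the
    signature of persistent individual movement styles.
    """
    a, b = M4.shape[0], M4.shape[1]
    if b < 2:
        raise ValueError("need at least 2 days for within-hen comparisons")
    iu = np.triu_indices(b, k=1)
    rows = []
    for i in range(a):
        within = np.median(M4[i][:, i, :][iu])
        mask = np.ones(a, dtype=bool)
        mask[i] = False
        between = np.median(M4[i][:, mask, :])
        rows.append((i, within, between))
    per_hen = pd.DataFrame(rows, columns=["hen", "median_within", "median_between"])
    if hens is not None:
        per_hen["hen_id"] = [hens[i] for i in per_hen.hen]
    diffs = per_hen.median_within - per_hen.median_between
    if np.allclose(diffs, 0):
        return WithinBetweenResult(per_hen, np.nan, np.nan, degenerate=True)
    V, p = stats.wilcoxon(
        per_hen.median_within, per_hen.median_between, alternative="less"
    )
    return WithinBetweenResult(per_hen, float(V), float(p))


@dataclass
class ClusterAssignment:
    labels: dict  # hen_id (or index) -> 1..k
    k: int
    method: str
    record: list  # per split/merge bookkeeping
    silhouette: float | None = None


def diana_labels(D: np.ndarray, k: int) -> np.ndarray:
    """Divisive analysis (Diana) clustering of a distance matrix, cut at k.

    Macnaughton-Smith splintering: repeatedly split the cluster with the
    largest diameter by seeding a splinter group with the object of
    maximal average dissimilarity and moving objects while their average
    dissimilarity to the splinter is smaller than to the remainder.
    Ties break towards the lowest index, making the result deterministic.
    """
    n = D.shape[0]
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        ci = int(np.argmax(diams))
        if diams[ci] == 0.0:
            # all remaining clusters are tied/zero-diameter: split off the
            # lowest-index member of the first splittable cluster
            ci = next(i for i, c in enumerate(clusters) if len(c) > 1)
        old = clusters[ci]
        sub = D[np.ix_(old, old)]
        mean_d = sub.sum(axis=1) / (len(old) - 1)
        splinter = [int(np.argmax(mean_d == mean_d.max()))]  # lowest index on ties
        rest = [i for i in range(len(old)) if i != splinter[0]]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            best_gain, best_obj = 0.0, None
            for o in rest:
                d_rest = sub[o, [r for r in rest if r != o]].mean()
                d_spl = sub[o, splinter].mean()
                gain = d_rest - d_spl
                if gain > best_gain + 1e-12:
                    best_gain, best_obj = gain, o
            if best_obj is not None:
                rest.remove(best_obj)
                splinter.append(best_obj)
                moved = True
        clusters[ci] = [old[i] for i in sorted(splinter)]
        clusters.append([old[i] for i in sorted(rest)])
    labels = np.zeros(n, dtype=np.int64)
    # stable label order: by lowest member index
    for lab, c in enumerate(sorted(clusters, key=min), start=1):
        labels[c] = lab
    return labels


def cluster_hens(
    A: np.ndarray,
    k: int | None = None,
    hens: list[str] | None = None,
    method: str = "diana",
    k_range: tuple[int, int] = (2, 6),
    summaries: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """Cluster hens on the summed dyadic DTW matrix.

    ``method`` is ``"diana"`` (divisive, default) or ``"complete"``
    (agglomerative complete linkage).  With ``k=None`` the cut is chosen
    by silhouette score over ``k_range``.  When a per-hen ``summaries``
    frame is given, per-cluster means are attached to ``record``.
    """
    A = np.asarray(A, dtype=float)
    a = A.shape[0]
    if k is not None and (k < 2 or k > a):
        raise ValueError("k must be in 2..n_hens")

    def labels_for(kk: int) -> np.ndarray:
        if method == "diana":
            return diana_labels(A, kk)
        if method == "complete":
            Z = linkage(squareform(A, checks=False), method="complete")
            return fcluster(Z, kk, criterion="maxclust")
        raise ValueError(f"unknown method {method!r}")

    sil = None
    if k is None:
        best = None
        for kk in range(k_range[0], min(k_range[1], a - 1) + 1):
            lab = labels_for(kk)
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(A, lab, metric="precomputed")
            if best is None or s > best[0]:
                best = (s, kk, lab)
        if best is None:
            raise ValueError("could not select k automatically")
        sil, k, lab = best
    else:
        lab = labels_for(k)

    keys = hens if hens is not None else list(range(a))
    record: list = []
    if summaries is not None and hens is not None:
        tmp = summaries.set_index("hen_id").copy()
        tmp["cluster"] = [lab[hens.index(h)] for h in tmp.index]
        record.append(tmp.groupby("cluster").mean(numeric_only=True).reset_index())
    return ClusterAssignment(
        labels={h: int(l) for h, l in zip(keys, lab)},
        k=int(k),
        method=method,
        record=record,
        silhouette=sil,
    )


@dataclass
class TrendFit:
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    p: float
    r2_adj: float
    daily_means: np.ndarray


def daily_dissimilarity_trend(daily: np.ndarray) -> TrendFit:
    """OLS linear trend of the daily mean cross-hen DTW dissimilarity.

    ``daily`` is the (b, a, a) stack of same-day distance matrices.  The
    per-day mean over distinct hen pairs is regressed on day number; a
    flat trend indicates stable daily movement patterns at flock level.
    """
    b, a = daily.shape[0], daily.shape[1]
    if b < 3:
        raise ValueError("need at least 3 days for a trend")
    iu = np.triu_indices(a, k=1)
    means = np.array([daily[d][iu].mean() for d in range(b)])
    day = np.arange(b, dtype=float)
    res = stats.linregress(day, means)
    dof = (1, b - 2)
    if np.isnan(res.rvalue):
        F, p, r2a = 0.0, 1.0, 0.0
    else:
        r2 = res.rvalue**2
        F = r2 / max(1 - r2, 1e-300) * dof[1]
        p = float(stats.f.sf(F, *dof)) if 1 - r2 > 1e-300 else 0.0
        r2a = 1 - (1 - r2) * (b - 1) / (b - 2)
    return TrendFit(float(res.slope), float(res.intercept), float(F), dof, p, float(r2a), means)
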