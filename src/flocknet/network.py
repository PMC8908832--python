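"""Co-occurrence association networks at the gate antennas.

Two hens are associated (a dyadic point event) when they pass the same
antenna -- same gate, same direction -- within a closed 5 s window.
Registration counts A, B and co-occurrence counts AB combine into the
Jaccard-type association index AI = AB / (A + B - AB) in [0, 1], built
per day and pooled over the whole period.  On top of the AI matrices the
module provides the dyadic-strength null CDF (label-permutation null),
Newman-Girvan community detection with weighted modularity and
by-community assortativity, weighted PageRank, the temporal
autocorrelation of daily networks, and down-sampling robustness checks.

Counting rule: within a dyad, events pair one-to-one by greedy
time-ordered matching, so AB <= min(A, B) and AI stays in [0, 1]; one
registration can still co-occur with several *different* partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CooccurrenceCounts",
    "detect_cooccurrences",
    "association_matrix",
    "daily_association_matrices",
    "StrengthNullResult",
    "strength_null_cdf",
    "CommunityPartition",
    "detect_communities",
    "pagerank_centrality",
    "network_autocorrelation",
    "downsampling_robustness",
]

DEFAULT_WINDOW = 5  # seconds; closed (<=) co-occurrence window


@dataclass
class CooccurrenceCounts:
    hens: list[str]
    A: np.ndarray  # per-hen gate-passage count in the period
    AB: np.ndarray  # (a, a) symmetric dyadic co-occurrence counts


def _match_counts(times_by_hen: dict, window: float) -> dict:
    """Greedy one-to-one matching of event times per dyad; AB counts."""
    hens = sorted(times_by_hen)
    counts: dict = {}
    for ii, h1 in enumerate(hens):
        t1 = times_by_hen[h1]
        for h2 in hens[ii + 1 :]:
            t2 = times_by_hen[h2]
            i = j = c = 0
            while i < len(t1) and j < len(t2):
                d = t1[i] - t2[j]
                if abs(d) <= window:
                    c += 1
                    i += 1
                    j += 1
                elif d < 0:
                    i += 1
                else:
                    j += 1
            if c:
                counts[(h1, h2)] = counts.get((h1, h2), 0) + c
    return counts


def detect_cooccurrences(
    transitions: pd.DataFrame,
    hens: list[str],
    window: float = DEFAULT_WINDOW,
) -> CooccurrenceCounts:
    """Count dyadic co-occurrences at gate antennas.

    Each transition is one registration at its entry-side antenna
    (gate + direction); two hens co-occur when registered at the same
    antenna on the same day within ``window`` seconds (closed bound).
    """
    if window <= 0:
        raise ValueError("co-occurrence window must be positive")
    pos = {h: i for i, h in enumerate(hens)}
    a = len(hens)
    A = np.zeros(a, dtype=np.int64)
    AB = np.zeros((a, a), dtype=np.int64)
    df = transitions[transitions.hen_id.isin(pos.keys())]
    for h, n in df.groupby("hen_id").size().items():
        A[pos[h]] = n
    gate = np.minimum(df.from_area, df.to_area)
    for _, grp in df.groupby([df.day, gate, df.to_area], sort=False):
        tb = {
            h: np.sort(g.time_s.to_numpy(dtype=float))
            for h, g in grp.groupby("hen_id", sort=True)
        }
        if len(tb) < 2:
            continue
        for (h1, h2), c in _match_counts(tb, window).items():
            i, j = pos[h1], pos[h2]
            AB[i, j] += c
            AB[j, i] += c
    return CooccurrenceCounts(list(hens), A, AB)


def association_matrix(counts: CooccurrenceCounts) -> np.ndarray:
    """Association index AI = AB / (A + B - AB), symmetric, zero diagonal.

    Dyads whose denominator is zero (neither hen ever registered) get 0.
    """
    A, AB = counts.A, counts.AB
    if (AB > np.minimum(A[:, None], A[None, :])).any():
        raise ValueError("AB exceeds min(A, B): counting invariant violated")
    denom = A[:, None] + A[None, :] - AB
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom > 0, AB / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(ai, 0.0)
    return ai


def daily_association_matrices(
    transitions: pd.DataFrame,
    hens: list[str],
    window: float = DEFAULT_WINDOW,
) -> dict[int, np.ndarray]:
    """AI matrix per day (counts restricted to that day)."""
    return {
        int(day): association_matrix(detect_cooccurrences(grp, hens, window))
        for day, grp in transitions.groupby("day", sort=True)
    }


@dataclass
class StrengthNullResult:
    observed: np.ndarray  # sorted observed dyadic AI values
    null_values: list[np.ndarray]  # per permutation, sorted dyadic AI values
    grid: np.ndarray
    observed_cdf: np.ndarray
    null_low: np.ndarray  # 2.5% envelope of null CDFs on grid
    null_high: np.ndarray  # 97.5% envelope
    ks: float
    p: float


def strength_null_cdf(
    transitions: pd.DataFrame,
    hens: list[str],
    n_perm: int = 200,
    window: float = DEFAULT_WINDOW,
    seed: int = 0,
) -> StrengthNullResult:
    """Observed dyadic-strength CDF against a label-permutation null.

    The null randomly reallocates hen labels across registrations --
    keeping every event time/antenna and each hen's total registration
    count -- and recomputes the AI matrix per permutation.  Real social
    preference shows up as an excess of high-AI dyads above the null
    envelope.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(hens), k=1)
    obs = np.sort(association_matrix(detect_cooccurrences(transitions, hens, window))[iu])
    labels = transitions.hen_id.to_numpy()
    null_vals = []
    perm_df = transitions.copy()
    for _ in range(n_perm):
        perm_df["hen_id"] = rng.permutation(labels)
        ai = association_matrix(detect_cooccurrences(perm_df, hens, window))
        null_vals.append(np.sort(ai[iu]))
    hi = max(obs.max(initial=0.0), max(v.max(initial=0.0) for v in null_vals), 1e-9)
    grid = np.linspace(0.0, hi, 200)
    obs_cdf = np.searchsorted(obs, grid, side="right") / len(obs)
    null_cdfs = np.stack(
        [np.searchsorted(v, grid, side="right") / len(v) for v in null_vals]
    )
    pooled = np.concatenate(null_vals)
    ks, p = stats.ks_2samp(obs, pooled)
    return StrengthNullResult(
        observed=obs,
        null_values=null_vals,
        grid=grid,
        observed_cdf=obs_cdf,
        null_low=np.quantile(null_cdfs, 0.025, axis=0),
        null_high=np.quantile(null_cdfs, 0.975, axis=0),
        ks=float(ks),
        p=float(p),
    )


def _graph_from_matrix(ai: np.ndarray, hens: list[str]) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(hens)
    a = len(hens)
    for i in range(a):
        for j in range(i + 1, a):
            if ai[i, j] > 0:
                G.add_edge(hens[i], hens[j], weight=float(ai[i, j]), distance=1.0 / float(ai[i, j]))
    return G


def community_assortativity(ai: np.ndarray, labels: np.ndarray) -> float:
    """Weighted assortativity by community: r = (tr e - sum e^2)/(1 - sum e^2).

    ``e`` is the community mixing matrix of edge weight fractions.
    Returns 0 for a graph with no edge weight.
    """
    labs = np.unique(labels)
    k = len(labs)
    idx = {l: i for i, l in enumerate(labs)}
    e = np.zeros((k, k))
    a = ai.shape[0]
    for i in range(a):
        for j in range(i + 1, a):
            w = ai[i, j]
            if w > 0:
                gi, gj = idx[labels[i]], idx[labels[j]]
                e[gi, gj] += w
                e[gj, gi] += w
    tot = e.sum()
    if tot == 0:
        return 0.0
    e /= tot
    ab = (e.sum(axis=0) * e.sum(axis=1)).sum()
    if ab >= 1.0:
        return 0.0
    return float((np.trace(e) - ab) / (1.0 - ab))


@dataclass
class CommunityPartition:
    labels: dict  # hen_id -> community index (0-based)
    modularity: float
    assortativity: float
    n_communities: int


def detect_communities(ai: np.ndarray, hens: list[str]) -> CommunityPartition:
    """Newman-Girvan communities on the weighted association graph.

    Edges are removed in order of highest edge betweenness (with AI
    converted to a distance 1/AI for the shortest-path computation); the
    partition with maximal weighted modularity across the divisive
    sequence is returned, together with the by-community assortativity.
    """
    G = _graph_from_matrix(ai, hens)
    if G.number_of_edges() == 0:
        labels = {h: i for i, h in enumerate(hens)}
        return CommunityPartition(labels, 0.0, 0.0, len(hens))

    def heaviest_betweenness(g):
        bet = nx.edge_betweenness_centrality(g, weight="distance")
        return max(bet, key=lambda e: (bet[e], e))

    best = None
    # the iterator starts past the initial partition, so seed the candidate
    # set with the one-community partition and the connected components
    for comms in [[set(G.nodes)], list(nx.connected_components(G))]:
        q = nx.community.modularity(G, comms, weight="weight")
        if best is None or q > best[0]:
            best = (q, comms)
    for comms in nx.community.girvan_newman(G, most_valuable_edge=heaviest_betweenness):
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best[0]:
            best = (q, comms)
    q, comms = best
    labels = {}
    for ci, c in enumerate(sorted((sorted(c) for c in comms), key=lambda c: c[0])):
        for h in c:
            labels[h] = ci
    lab_arr = np.array([labels[h] for h in hens])
    return CommunityPartition(
        labels, float(q), community_assortativity(ai, lab_arr), int(lab_arr.max() + 1)
    )


def pagerank_centrality(ai: np.ndarray, hens: list[str], damping: float = 0.85) -> pd.Series:
    """Weighted PageRank scores (sum to 1); uniform on an empty graph."""
    if (ai < 0).any():
        raise ValueError("association weights must be nonnegative")
    G = _graph_from_matrix(ai, hens)
    if G.number_of_edges() == 0:
        return pd.Series(1.0 / len(hens), index=hens, name="pagerank")
    pr = nx.pagerank(G, alpha=damping, weight="weight")
    return pd.Series([pr[h] for h in hens], index=hens, name="pagerank")


def _upper(mat: np.ndarray, iu) -> np.ndarray:
    return mat[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def network_autocorrelation(
    daily: list[np.ndarray],
    lags: range | list[int],
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Temporal autocorrelation of daily association networks.

    For each lag tau, the Pearson correlation of the vectorized upper
    triangles of the day-d and day-(d+tau) matrices, averaged over d,
    with a 95% CI over day pairs.  The null band permutes hen labels of
    one matrix per pair; stable social structure puts the observed curve
    above the band at all lags.
    """
    D = len(daily)
    lags = list(lags)
    if max(lags) >= D:
        raise ValueError("largest lag must be smaller than the number of days")
    a = daily[0].shape[0]
    iu = np.triu_indices(a, k=1)
    rng = np.random.default_rng(seed)
    rows = []
    for tau in lags:
        rs = [
            r
            for d in range(D - tau)
            if not np.isnan(r := _pearson(daily[d][iu], daily[d + tau][iu]))
        ]
        rs = np.array(rs)
        mean_r = rs.mean() if len(rs) else np.nan
        if len(rs) > 1:
            half = stats.t.ppf(0.975, len(rs) - 1) * rs.std(ddof=1) / np.sqrt(len(rs))
        else:
            half = np.nan
        null_means = []
        for _ in range(n_perm):
            nrs = []
            for d in range(D - tau):
                p = rng.permutation(a)
                r = _pearson(daily[d][iu], daily[d + tau][np.ix_(p, p)][iu])
                if not np.isnan(r):
                    nrs.append(r)
            if nrs:
                null_means.append(np.mean(nrs))
        null_means = np.array(null_means)
        rows.append(
            {
                "lag": tau,
                "r_mean": mean_r,
                "ci_low": mean_r - half,
                "ci_high": mean_r + half,
                "null_mean": null_means.mean(),
                "null_low": np.quantile(null_means, 0.025),
                "null_high": np.quantile(null_means, 0.975),
                "n_pairs": len(rs),
            }
        )
    return pd.DataFrame(rows)


def downsampling_robustness(
    transitions: pd.DataFrame,
    hens: list[str],
    fractions: list[float],
    n_reps: int = 10,
    window: float = DEFAULT_WINDOW,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of network measures under hen subsampling.

    For each fraction, hens are subsampled without replacement and the
    pooled network is recomputed; reported per replicate: density
    (fraction of nonzero dyads), mean AI over dyads, weighted modularity
    of the Newman-Girvan partition, and the Pearson correlation of the
    retained hens' PageRank with their full-sample values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    full_ai = association_matrix(detect_cooccurrences(transitions, hens, window))
    full_pr = pagerank_centrality(full_ai, hens)
    rows = []
    for frac in fractions:
        m = int(round(frac * len(hens)))
        if m < 3:
            continue
        for rep in range(n_reps):
            keep = sorted(rng.choice(len(hens), size=m, replace=False))
            sub_hens = [hens[i] for i in keep]
            sub = transitions[transitions.hen_id.isin(sub_hens)]
            ai = association_matrix(detect_cooccurrences(sub, sub_hens, window))
            iu = np.triu_indices(m, k=1)
            vals = ai[iu]
            part = detect_communities(ai, sub_hens)
            pr = pagerank_centrality(ai, sub_hens)
            rows.append(
                {
                    "fraction": frac,
                    "rep": rep,
                    "n_hens": m,
                    "density": float((vals > 0).mean()),
                    "mean_ai": float(vals.mean()),
                    "modularity": part.modularity,
                    "pagerank_r": _pearson(pr.to_numpy(), full_pr[sub_hens].to_numpy()),
                }
            )
    return pd.DataFrame(rows)
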