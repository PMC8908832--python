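"""Curation of raw gate registrations into analysable movement data.

A full gate passage produces two registrations (exit-side antenna, then
entry-side).  Missed detections leave single-read passages, or drop
passages entirely; the curation rules are:

* paired exit/entry reads at one gate collapse to one transition,
  timestamped at the entry-side read;
* a single surviving read still identifies the passage (direction is
  resolved from the hen's tracked current area);
* when consecutive located areas are non-adjacent on the chain, the m
  missing transitions are interpolated at evenly spaced interior points
  between the bracketing known times (fractions 1/(m+1) ... m/(m+1));
  a single missing transition therefore falls at the midpoint;
* sojourn intervals are only emitted where both the entry and the exit
  registration of the stay were actually recorded.

From curated transitions the module builds per-hen-day area-occupancy
series (ordinal codes 1=IN .. 4=FR sampled on a fixed bin grid), the
leading index, sample entropy, the gap-time coordination test against a
uniform U(a, b) null, and per-hen summary metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .areas import AREAS, N_AREAS, chain_path, default_gate_map

__all__ = [
    "pair_registrations",
    "extract_sojourns",
    "drop_final_window",
    "build_daily_series",
    "build_series_array",
    "leading_index",
    "sample_entropy",
    "GapTimeResult",
    "gap_time_coordination_test",
    "gap_time_tests",
    "compute_hen_summary",
]

PAIR_WINDOW = 5  # max seconds between the two reads of one passage

TRANSITION_COLS = ["hen_id", "day", "time_s", "from_area", "to_area", "interpolated"]


def _check_sorted(events: pd.DataFrame) -> None:
    bad = (
        events.groupby(["hen_id", "day"], sort=False)["time_s"]
        .apply(lambda t: bool((np.diff(t.to_numpy()) < 0).any()))
    )
    if bad.any():
        key = bad[bad].index[0]
        raise ValueError(f"non-monotone timestamps for hen {key[0]} on day {key[1]}")


def _hen_day_transitions(times, sides, gates, gate_map_areas) -> list[tuple]:
    """State machine for one hen-day; returns (time, from, to, interpolated)."""
    out: list[tuple] = []
    cur = 1  # all hens start the day indoors
    last_t = 0.0

    def interpolate_to(target: int, t_next: float) -> None:
        nonlocal cur, last_t
        path = chain_path(cur, target)
        m = len(path) - 1
        if m <= 0:
            return
        for step in range(1, m + 1):
            ti = last_t + (t_next - last_t) * step / (m + 1)
            out.append((ti, path[step - 1], path[step], True))
        cur = target
        last_t = out[-1][0]

    i = 0
    nrec = len(times)
    while i < nrec:
        t, side, gate = times[i], sides[i], gates[i]
        lo, hi = gate_map_areas[gate]
        # try to pair with the next read: same gate, other side, close in time
        if (
            i + 1 < nrec
            and gates[i + 1] == gate
            and sides[i + 1] != side
            and times[i + 1] - t <= PAIR_WINDOW
        ):
            frm, to, t_pass = side, sides[i + 1], float(times[i + 1])
            i += 2
        else:
            other = hi if side == lo else lo
            if cur == side:
                frm, to = side, other  # exit-side read of a passage out of cur
            elif cur == other:
                frm, to = other, side  # entry-side read of a passage into side
            else:
                # hen was last located away from this gate: approach via the
                # near side, cross towards the far side
                near = lo if abs(lo - cur) < abs(hi - cur) else hi
                frm, to = near, (hi if near == lo else lo)
            t_pass = float(t)
            i += 1
        if frm != cur:
            interpolate_to(frm, t_pass)
        out.append((t_pass, frm, to, False))
        cur = to
        last_t = t_pass
    return out


def pair_registrations(
    events: pd.DataFrame,
    roster: list[str] | None = None,
    gate_map: dict | None = None,
) -> pd.DataFrame:
    """Collapse raw registrations into one transition per gate passage.

    Parameters
    ----------
    events : DataFrame with columns day, time_s, hen_id, antenna_id,
        time-sorted within each hen-day.
    roster : known hen ids; records for unknown hens are skipped and
        counted in the QC tally (``result.attrs['qc']``).
    gate_map : antenna -> {gate, side_area, areas}; defaults to the
        4-area chain shipped with the package.

    Returns a DataFrame with columns hen_id, day, time_s, from_area,
    to_area, interpolated.
    """
    gate_map = gate_map or default_gate_map()
    qc = {"n_records": len(events), "unknown_hen": 0, "unknown_antenna": 0}

    known_ant = events.antenna_id.isin(gate_map.keys())
    qc["unknown_antenna"] = int((~known_ant).sum())
    events = events[known_ant]
    if roster is not None:
        in_roster = events.hen_id.isin(set(roster))
        qc["unknown_hen"] = int((~in_roster).sum())
        if qc["unknown_hen"]:
            warnings.warn(f"skipped {qc['unknown_hen']} records of unknown hens")
        events = events[in_roster]
    _check_sorted(events)

    side_of = {a: info["side_area"] for a, info in gate_map.items()}
    gate_of = {a: info["gate"] for a, info in gate_map.items()}
    areas_of_gate = {info["gate"]: tuple(sorted(info["areas"])) for info in gate_map.values()}

    rows: list[tuple] = []
    for (hen, day), grp in events.groupby(["hen_id", "day"], sort=True):
        times = grp.time_s.to_numpy(dtype=float)
        sides = [side_of[a] for a in grp.antenna_id]
        gates = [gate_of[a] for a in grp.antenna_id]
        for t, frm, to, interp in _hen_day_transitions(times, sides, gates, areas_of_gate):
            rows.append((hen, day, t, frm, to, interp))

    out = pd.DataFrame(rows, columns=TRANSITION_COLS)
    out = out.sort_values(["day", "time_s", "hen_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["qc"] = qc
    return out


def extract_sojourns(
    events: pd.DataFrame,
    roster: list[str] | None = None,
    gate_map: dict | None = None,
) -> pd.DataFrame:
    """Completed stays: both the entry and the exit registration recorded.

    A sojourn in area A runs from the entry-side read of the passage
    into A to the exit-side read of the next passage out of A, with no
    interpolated (i.e. undetected) passage in between.  Incomplete stays
    are silently excluded and counted in ``result.attrs['qc']``.
    """
    gate_map = gate_map or default_gate_map()
    side_of = {a: info["side_area"] for a, info in gate_map.items()}
    gate_of = {a: info["gate"] for a, info in gate_map.items()}

    qc = {"incomplete_stays": 0}
    rows: list[tuple] = []
    if roster is not None:
        events = events[events.hen_id.isin(set(roster))]
    events = events[events.antenna_id.isin(side_of.keys())]
    _check_sorted(events)

    for (hen, day), grp in events.groupby(["hen_id", "day"], sort=True):
        times = grp.time_s.to_numpy(dtype=float)
        sides = [side_of[a] for a in grp.antenna_id]
        gates = [gate_of[a] for a in grp.antenna_id]
        # passages with read-level detail: (t, frm, to, has_exit_read, has_entry_read, t_exit, t_entry)
        passages: list[tuple] = []
        i = 0
        while i < len(times):
            if (
                i + 1 < len(times)
                and gates[i + 1] == gates[i]
                and sides[i + 1] != sides[i]
                and times[i + 1] - times[i] <= PAIR_WINDOW
            ):
                passages.append((sides[i], sides[i + 1], times[i], times[i + 1]))
                i += 2
            else:
                passages.append(None)  # single read: one side unconfirmed
                i += 1
        for p, q in zip(passages, passages[1:]):
            if p is None or q is None:
                qc["incomplete_stays"] += 1
                continue
            area = p[1]
            if q[0] != area:  # undetected passage(s) in between
                qc["incomplete_stays"] += 1
                continue
            t_enter, t_exit = p[3], q[2]
            if t_exit > t_enter:
                rows.append((hen, day, area, t_enter, t_exit))
    out = pd.DataFrame(rows, columns=["hen_id", "day", "area", "t_enter", "t_exit"])
    out.attrs["qc"] = qc
    return out


def drop_final_window(
    transitions: pd.DataFrame, day_length: int, window: int = 300
) -> pd.DataFrame:
    """Exclude transitions in the final ``window`` seconds of the day.

    Passages just before pop-hole closing can reflect shooing-in rather
    than free movement; they are retained by default throughout the
    package (they are a negligible share of passages) and this filter
    is opt-in.
    """
    return transitions[transitions.time_s < day_length - window].copy()


def build_daily_series(
    transitions: pd.DataFrame,
    hen_id: str,
    day: int,
    bin: int = 60,
    day_open: int = 0,
    day_close: int | None = None,
) -> np.ndarray:
    """Area-occupancy series of one hen-day, sampled every ``bin`` seconds.

    The hen starts the day in IN (code 1); an area change takes effect
    at the first bin boundary at or after the transition time.  Length
    is ``floor((day_close - day_open) / bin)``.
    """
    if day_close is None:
        raise ValueError("day_close is required")
    sub = transitions[(transitions.hen_id == hen_id) & (transitions.day == day)]
    t = sub.time_s.to_numpy(dtype=float)
    if len(t) and ((t < day_open).any() or (t >= day_close).any()):
        raise ValueError("transition outside the [day_open, day_close) window")
    return _series_from_arrays(
        t, sub.to_area.to_numpy(), bin, day_open, day_close
    )


def _series_from_arrays(times, to_area, bin, day_open, day_close) -> np.ndarray:
    L = (day_close - day_open) // bin
    grid = day_open + np.arange(L) * bin
    if len(times) == 0:
        return np.ones(L, dtype=np.int8)
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    path = np.concatenate(([1], np.asarray(to_area)[order]))
    idx = np.searchsorted(times, grid, side="right")
    return path[idx].astype(np.int8)


def build_series_array(
    transitions: pd.DataFrame,
    hens: list[str],
    n_days: int,
    bin: int,
    day_length: int,
    include_interpolated: bool = True,
) -> np.ndarray:
    """All hen-day series as an (a, b, L) int8 array (1-based area codes)."""
    if not include_interpolated:
        transitions = transitions[~transitions.interpolated]
    L = day_length // bin
    out = np.ones((len(hens), n_days, L), dtype=np.int8)
    hen_pos = {h: i for i, h in enumerate(hens)}
    for (hen, day), grp in transitions.groupby(["hen_id", "day"], sort=False):
        i = hen_pos.get(hen)
        if i is None or not (0 <= day < n_days):
            continue
        out[i, day] = _series_from_arrays(
            grp.time_s.to_numpy(dtype=float), grp.to_area.to_numpy(), bin, 0, day_length
        )
    return out


def leading_index(transitions: pd.DataFrame) -> pd.Series:
    """Fraction of a hen's gate passages where it was leading, per hen.

    Within each (day, gate, direction) sequence of passages ordered by
    time, a passage is *leading* when the gap to the hen ahead exceeds
    the gap to the hen behind.  Passages lacking either neighbour are
    excluded from numerator and denominator; hens with no eligible
    passage get NaN.
    """
    df = transitions.copy()
    df["gate"] = np.minimum(df.from_area, df.to_area)
    lead = {}
    elig = {}
    for _, grp in df.groupby(["day", "gate", "to_area"], sort=False):
        if len(grp) < 3:
            continue
        grp = grp.sort_values("time_s", kind="mergesort")
        t = grp.time_s.to_numpy(dtype=float)
        gap_before = t[1:-1] - t[:-2]
        gap_after = t[2:] - t[1:-1]
        for hen, gb, ga in zip(grp.hen_id.to_numpy()[1:-1], gap_before, gap_after):
            elig[hen] = elig.get(hen, 0) + 1
            if gb > ga:
                lead[hen] = lead.get(hen, 0) + 1
    hens = sorted(set(transitions.hen_id))
    return pd.Series(
        {h: (lead.get(h, 0) / elig[h]) if elig.get(h) else np.nan for h in hens},
        name="leading_index",
    )


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) of a 1-D series.

    SampEn = -ln(A/B), where B counts template pairs of length m within
    Chebyshev tolerance r (self-matches excluded) and A the same for
    length m+1.  Returns 0 for a constant series, +inf when A == 0.
    ``r`` defaults to 0.2 times the series SD.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) <= m + 1:
        raise ValueError("series must be 1-D with length > m + 1")
    if r is not None and r <= 0:
        raise ValueError("tolerance r must be positive")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = 0.2 * x.std()

    # pairs are restricted to the N - m templates so that every length-m
    # template has a length-(m+1) continuation (standard SampEn convention)
    n_tpl = len(x) - m
    tpl_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_tpl]
    B = 0
    for i in range(n_tpl - 1):
        d = np.abs(tpl_m[i + 1 :] - tpl_m[i]).max(axis=1)
        B += int((d <= r).sum())
    tpl_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    A = 0
    for i in range(len(tpl_m1) - 1):
        d = np.abs(tpl_m1[i + 1 :] - tpl_m1[i]).max(axis=1)
        A += int((d <= r).sum())
    if B == 0:
        return np.inf
    if A == 0:
        return np.inf
    return float(-np.log(A / B))


@dataclass
class GapTimeResult:
    """Observed vs uniform-null gap times of one gate-direction-day."""

    day: int
    gate: int
    to_area: int
    k: int  # number of transitions
    observed: np.ndarray
    expected: np.ndarray
    ks: float
    p: float


def gap_time_coordination_test(
    times: np.ndarray, n_draws: int = 100, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Test one stream of gate-passage times for temporal coordination.

    The null of uncoordinated movement draws k points uniformly on
    [a, b] (a, b = first and last observed time), ``n_draws`` times, and
    pools their gaps; a two-sample KS test compares observed gaps with
    the pooled null gaps.  Coordinated (bursty) movement shows an excess
    of short gaps.
    """
    t = np.sort(np.asarray(times, dtype=float))
    k = len(t)
    if k < 2:
        raise ValueError("need at least 2 transitions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = t[0], t[-1]
    obs = np.diff(t)
    sim = np.sort(rng.uniform(a, b, size=(n_draws, k)), axis=1)
    exp = np.diff(sim, axis=1).ravel()
    ks, p = stats.ks_2samp(obs, exp)
    return obs, exp, float(ks), float(p)


def gap_time_tests(
    transitions: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
    min_k: int = 2,
) -> list[GapTimeResult]:
    """Run the gap-time coordination test per (day, gate, direction).

    Gate-days with fewer than ``min_k`` transitions are skipped (tallied
    on the returned list's ``.skipped`` is not possible; a notice is
    issued via warnings when any group is skipped).
    """
    df = transitions.copy()
    df["gate"] = np.minimum(df.from_area, df.to_area)
    rng = np.random.default_rng(seed)
    out: list[GapTimeResult] = []
    skipped = 0
    for (day, gate, to_area), grp in df.groupby(["day", "gate", "to_area"], sort=True):
        t = grp.time_s.to_numpy(dtype=float)
        if len(t) < max(min_k, 2):
            skipped += 1
            continue
        obs, exp, ks, p = gap_time_coordination_test(t, n_draws=n_draws, seed=rng)
        out.append(GapTimeResult(day, gate, to_area, len(t), obs, exp, ks, p))
    if skipped:
        warnings.warn(f"skipped {skipped} gate-days with fewer than {min_k} transitions")
    return out


def _first_transition_ranks(
    transitions: pd.DataFrame, from_area: int, to_area: int, last: bool = False
) -> pd.DataFrame:
    """Per-day rank of each hen's first (or last) from->to transition."""
    sub = transitions[
        (transitions.from_area == from_area) & (transitions.to_area == to_area)
    ]
    if sub.empty:
        return pd.DataFrame(columns=["hen_id", "day", "rank"])
    agg = "max" if last else "min"
    per = sub.groupby(["day", "hen_id"], sort=False)["time_s"].agg(agg).reset_index()
    per["rank"] = per.groupby("day")["time_s"].rank(method="average")
    return per


def compute_hen_summary(
    transitions: pd.DataFrame,
    series: np.ndarray,
    hens: list[str],
    m: int = 2,
    r_factor: float = 0.2,
) -> pd.DataFrame:
    """Per-hen descriptive metrics.

    Columns: prop_IN/WG/SY/FR (fractions of located time, sum to 1),
    n_days_outside, n_transitions, leading_index, sample_entropy (mean
    of per-day SampEn at tolerance ``r_factor`` times the SD of the
    hen's concatenated series), mean_exit_rank (first WG->SY of the
    morning) and mean_return_rank (last SY->WG of the day).
    """
    a, b, L = series.shape
    if a != len(hens):
        raise ValueError("series/hens shape mismatch")
    lead = leading_index(transitions)
    exit_ranks = _first_transition_ranks(transitions, 2, 3, last=False)
    return_ranks = _first_transition_ranks(transitions, 3, 2, last=True)
    ntrans = transitions.groupby("hen_id").size()

    rows = []
    for i, hen in enumerate(hens):
        s = series[i]
        props = [(s == c).mean() for c in range(1, N_AREAS + 1)]
        concat = s.ravel().astype(float)
        sd = concat.std()
        if sd == 0:
            samp = 0.0
        else:
            r = r_factor * sd
            vals = [sample_entropy(s[d].astype(float), m=m, r=r) for d in range(b)]
            finite = [v for v in vals if np.isfinite(v)]
            samp = float(np.mean(finite)) if finite else np.inf
        er = exit_ranks.loc[exit_ranks.hen_id == hen, "rank"]
        rr = return_ranks.loc[return_ranks.hen_id == hen, "rank"]
        rows.append(
            {
                "hen_id": hen,
                **{f"prop_{name}": p for name, p in zip(AREAS, props)},
                "n_days_outside": int(((s > 1).any(axis=1)).sum()),
                "n_transitions": int(ntrans.get(hen, 0)),
                "leading_index": float(lead.get(hen, np.nan)),
                "sample_entropy": samp,
                "mean_exit_rank": float(er.mean()) if len(er) else np.nan,
                "mean_return_rank": float(rr.mean()) if len(rr) else np.nan,
            }
        )
    return pd.DataFrame(rows)
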