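"""Curation rules: pairing, interpolation, sojourns, series, descriptors."""

import numpy as np
import pandas as pd
import pytest

from conftest import events_frame
from flocknet.curation import (
    build_daily_series,
    build_series_array,
    compute_hen_summary,
    extract_sojourns,
    gap_time_coordination_test,
    gap_time_tests,
    leading_index,
    pair_registrations,
    sample_entropy,
)
from flocknet.synthetic import SimConfig, simulate_flock


def _trans(rows):
    return pd.DataFrame(
        rows, columns=["hen_id", "day", "time_s", "from_area", "to_area", "interpolated"]
    )


class TestPairRegistrations:
    def test_paired_reads_collapse_to_entry_side_timestamp(self):
        tr = pair_registrations(events_frame([(0, 100, "h0", "G1a"), (0, 103, "h0", "G1b")]), ["h0"])
        assert len(tr) == 1
        row = tr.iloc[0]
        assert (row.time_s, row.from_area, row.to_area, row.interpolated) == (103.0, 1, 2, False)

    def test_midpoint_interpolation_of_one_missing_passage(self):
        # hen enters WG at t=100; next evidence is the SY-side exit read at
        # t=300, so the unrecorded WG->SY passage is placed at the midpoint
        tr = pair_registrations(
            events_frame([(0, 98, "h0", "G1a"), (0, 100, "h0", "G1b"), (0, 300, "h0", "G3a")]),
            ["h0"],
        )
        got = list(zip(tr.time_s, tr.from_area, tr.to_area, tr.interpolated))
        assert got == [(100.0, 1, 2, False), (200.0, 2, 3, True), (300.0, 3, 4, False)]

    def test_multiple_missing_passages_evenly_spaced(self):
        # last located IN at day start; FR-side read at t=300 implies two
        # missing passages at the 1/3 and 2/3 points of the bracket
        tr = pair_registrations(events_frame([(0, 300, "h0", "G3b")]), ["h0"])
        got = list(zip(tr.time_s, tr.from_area, tr.to_area, tr.interpolated))
        assert got == [(100.0, 1, 2, True), (200.0, 2, 3, True), (300.0, 3, 4, False)]

    def test_interpolated_chains_keep_adjacency_and_order(self):
        cfg = SimConfig(n_hens=12, n_days=3, seed=8, p_miss=0.3)
        ev, truth = simulate_flock(cfg)
        tr = pair_registrations(ev, truth.hens)
        for _, grp in tr.groupby(["hen_id", "day"]):
            assert (np.diff(grp.time_s.to_numpy()) >= 0).all()
            assert (np.abs(grp.to_area - grp.from_area) == 1).all()
            assert (grp.from_area.to_numpy()[1:] == grp.to_area.to_numpy()[:-1]).all()
            assert grp.from_area.iloc[0] == 1

    def test_roundtrip_without_dropout_matches_ground_truth(self):
        cfg = SimConfig(n_hens=15, n_days=4, seed=21, p_miss=0.0)
        ev, truth = simulate_flock(cfg)
        tr = pair_registrations(ev, truth.hens)
        gt = truth.transitions[~truth.transitions.forced]
        got = tr[["hen_id", "day", "time_s", "from_area", "to_area"]].reset_index(drop=True)
        want = (
            gt[["hen_id", "day", "time_s", "from_area", "to_area"]]
            .astype({"time_s": float})
            .sort_values(["day", "time_s", "hen_id"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, want)
        assert not tr.interpolated.any()

    def test_unknown_hen_skipped_with_tally(self):
        with pytest.warns(UserWarning, match="unknown hens"):
            tr = pair_registrations(
                events_frame([(0, 10, "h0", "G1a"), (0, 40, "ghost", "G1a")]), ["h0"]
            )
        assert tr.attrs["qc"]["unknown_hen"] == 1
        assert set(tr.hen_id) == {"h0"}

    def test_non_monotone_stream_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            pair_registrations(
                events_frame([(0, 100, "h0", "G1a"), (0, 50, "h0", "G1b")]), ["h0"]
            )


class TestSojourns:
    def test_complete_stay_recorded(self):
        ev = events_frame(
            [(0, 98, "h0", "G1a"), (0, 100, "h0", "G1b"),
             (0, 250, "h0", "G1b"), (0, 252, "h0", "G1a")]
        )
        sj = extract_sojourns(ev, ["h0"])
        assert len(sj) == 1
        row = sj.iloc[0]
        assert (row.area, row.t_enter, row.t_exit) == (2, 100.0, 250.0)

    def test_stay_without_exit_not_emitted(self):
        ev = events_frame([(0, 98, "h0", "G1a"), (0, 100, "h0", "G1b")])
        assert len(extract_sojourns(ev, ["h0"])) == 0

    def test_no_events_gives_empty_frame(self):
        assert len(extract_sojourns(events_frame([]), ["h0"])) == 0

    def test_sojourns_consistent_with_series(self):
        """On covered bins a sojourn's area equals the series value."""
        cfg = SimConfig(n_hens=10, n_days=2, seed=13, p_miss=0.1)
        ev, truth = simulate_flock(cfg)
        tr = pair_registrations(ev, truth.hens)
        sj = extract_sojourns(ev, truth.hens)
        series = build_series_array(tr, truth.hens, cfg.n_days, 60, cfg.day_length)
        pos = {h: i for i, h in enumerate(truth.hens)}
        checked = 0
        for row in sj.itertuples():
            lo = int(np.ceil(row.t_enter / 60))
            hi = int(np.floor(row.t_exit / 60))
            if hi > lo:
                vals = series[pos[row.hen_id], row.day, lo:hi]
                assert (vals == row.area).all()
                checked += 1
        assert checked > 50


class TestDailySeries:
    def test_no_transitions_constant_indoors(self):
        s = build_daily_series(_trans([]), "h0", 0, bin=60, day_close=32400)
        assert len(s) == 540 and (s == 1).all()

    def test_transition_at_time_zero_applies_immediately(self):
        s = build_daily_series(
            _trans([("h0", 0, 0.0, 1, 2, False)]), "h0", 0, bin=60, day_close=600
        )
        assert (s == 2).all()

    def test_bin_boundary_rule(self):
        s = build_daily_series(
            _trans([("h0", 0, 90.0, 1, 2, False), ("h0", 0, 210.0, 2, 1, False)]),
            "h0", 0, bin=60, day_close=360,
        )
        assert s.tolist() == [1, 1, 2, 2, 1, 1]

    def test_transition_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            build_daily_series(
                _trans([("h0", 0, 700.0, 1, 2, False)]), "h0", 0, bin=60, day_close=600
            )


def test_drop_final_window_filters_late_passages():
    from flocknet.curation import drop_final_window

    tr = _trans(
        [("h0", 0, 100.0, 1, 2, False), ("h0", 0, 32250.0, 2, 1, False)]
    )
    kept = drop_final_window(tr, day_length=32400, window=300)
    assert kept.time_s.tolist() == [100.0]


class TestLeadingIndex:
    def test_middle_hen_not_leading(self):
        # gaps: before B = 2, after B = 8 -> B is following, not leading
        tr = _trans(
            [("A", 0, 10.0, 1, 2, False), ("B", 0, 12.0, 1, 2, False), ("C", 0, 20.0, 1, 2, False)]
        )
        li = leading_index(tr)
        assert li["B"] == 0.0
        assert np.isnan(li["A"]) and np.isnan(li["C"])  # no neighbours on one side

    def test_always_leading_hen_scores_one(self):
        rows = []
        for day in range(3):
            rows += [
                ("ahead", day, 100.0, 1, 2, False),
                ("focus", day, 200.0, 1, 2, False),
                ("behind", day, 201.0, 1, 2, False),
            ]
        assert leading_index(_trans(rows))["focus"] == 1.0

    def test_single_hen_undefined(self):
        li = leading_index(_trans([("A", 0, 10.0, 1, 2, False)]))
        assert np.isnan(li["A"])


class TestSampleEntropy:
    @staticmethod
    def _brute(x, m, r):
        """Naive O(n^2) template counting, independent of the implementation."""
        x = np.asarray(x, float)
        N = len(x)

        def count(mm, limit):
            c = 0
            for i in range(limit):
                for j in range(i + 1, limit):
                    if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                        c += 1
            return c

        B = count(m, N - m)
        A = count(m + 1, N - m)
        if A == 0 or B == 0:
            return np.inf
        return -np.log(A / B)

    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(50), m=2, r=0.2) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 5, size=40).astype(float)
        got = sample_entropy(x, m=2, r=0.5)
        want = self._brute(x, 2, 0.5)
        assert got == pytest.approx(want)

    def test_alternating_series_matches_enumeration(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2], float)
        assert sample_entropy(x, m=2, r=0.5) == pytest.approx(self._brute(x, 2, 0.5))

    def test_noise_less_predictable_than_periodic(self):
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(50):
            noise = rng.normal(size=120)
            periodic = np.sin(np.arange(120) * 2 * np.pi / 12) + rng.normal(0, 0.05, 120)
            if sample_entropy(noise, 2, 0.2 * noise.std()) > sample_entropy(
                periodic, 2, 0.2 * periodic.std()
            ):
                wins += 1
        assert wins >= 45

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            sample_entropy(np.ones(30), m=2, r=0.0)


class TestGapTimeCoordination:
    def test_evenly_spaced_times_reject_uniform_null(self):
        times = np.arange(0, 3000, 50.0)  # 60 perfectly regular passages
        _, _, _, p = gap_time_coordination_test(times, n_draws=200, seed=0)
        assert p < 0.01

    def test_uniform_times_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            t = np.sort(rng.uniform(0, 30000, size=40))
            _, _, _, p = gap_time_coordination_test(t, n_draws=40, seed=rng)
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.11

    def test_two_transitions_edge_case(self):
        obs, exp, ks, p = gap_time_coordination_test(np.array([10.0, 50.0]), n_draws=50, seed=0)
        assert len(obs) == 1 and len(exp) == 50
        assert 0 <= p <= 1

    def test_single_transition_rejected(self):
        with pytest.raises(ValueError):
            gap_time_coordination_test(np.array([10.0]))

    def test_groupwise_runner_skips_sparse_gate_days(self):
        tr = _trans([("A", 0, 10.0, 1, 2, False)])
        with pytest.warns(UserWarning, match="skipped"):
            assert gap_time_tests(tr) == []


class TestHenSummary:
    def test_sedentary_hen(self):
        series = np.ones((1, 3, 100), dtype=np.int8)
        out = compute_hen_summary(_trans([]), series, ["h0"])
        row = out.iloc[0]
        assert row.prop_IN == 1.0 and row.prop_WG == 0.0
        assert row.n_days_outside == 0 and row.n_transitions == 0
        assert row.sample_entropy == 0.0

    def test_proportions_sum_to_one(self, demo_sim):
        cfg, _, truth, transitions, series = demo_sim
        out = compute_hen_summary(transitions, series, truth.hens)
        props = out[["prop_IN", "prop_WG", "prop_SY", "prop_FR"]].sum(axis=1)
        assert np.allclose(props, 1.0)

    def test_first_morning_exiter_has_rank_one(self):
        rows = []
        for day in range(4):
            rows += [
                ("early", day, 1000.0, 2, 3, False),
                ("late", day, 2000.0, 2, 3, False),
            ]
        out = compute_hen_summary(
            _trans(rows), np.ones((2, 4, 10), dtype=np.int8), ["early", "late"]
        )
        assert out.set_index("hen_id").loc["early", "mean_exit_rank"] == 1.0
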