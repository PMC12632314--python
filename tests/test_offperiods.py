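"""ON/OFF segmentation rules, quorum detection, fallback mode, statistics."""

import numpy as np
import pytest

from conftest import (
    intervals_equal,
    iv_pairs,
    oracle_detect_global,
    oracle_fallback,
    oracle_segment_channel,
    random_spike_instance,
)
from onoff.config import OffParams
from onoff.offperiods import (
    detect_fallback,
    detect_global,
    match_events,
    off_statistics,
    segment_channel,
)
from onoff.types import IntervalSet, SpikeTrainSet

MS = 1e-3


class TestSegmentChannel:
    def test_printed_definition_single_off(self):
        t = np.array([0, 10, 20, 30, 100, 115, 130]) * MS
        on, off = segment_channel(t)
        assert iv_pairs(off) == [(pytest.approx(0.030), pytest.approx(0.100))]
        assert iv_pairs(on) == [(0.0, pytest.approx(0.030)),
                                (pytest.approx(0.100), pytest.approx(0.130))]

    def test_gaps_below_50ms_are_not_off(self):
        t = np.array([0, 10, 20, 30, 75, 120, 135, 150]) * MS  # gaps 45 ms
        _, off = segment_channel(t)
        assert len(off) == 0

    def test_one_sided_flanking_accepts_single_spike_neighbour(self):
        # two gaps, each flanked by one long run and one single-spike run
        t = np.array([0, 10, 20, 30, 100, 200, 210, 220, 230]) * MS
        _, off = segment_channel(t)
        assert intervals_equal(iv_pairs(off), [(0.030, 0.100), (0.100, 0.200)])

    def test_both_flank_reading_rejects_single_spike_neighbour(self):
        t = np.array([0, 10, 20, 30, 100, 200, 210, 220, 230]) * MS
        _, off = segment_channel(t, OffParams(both_flanks=True))
        assert len(off) == 0

    def test_isi_exactly_50ms_breaks_the_run(self):
        # the ISI bound is exclusive: >= 50 ms ends an ON period
        t = np.array([0.0, 0.030, 0.080, 0.130])
        on, _ = segment_channel(t)
        assert len(on) == 3  # runs split at both 50 ms ISIs

    def test_empty_train_yields_nothing(self):
        on, off = segment_channel(np.empty(0))
        assert len(on) == 0 and len(off) == 0

    def test_matches_bruteforce_scanner_on_random_trains(self):
        rng = np.random.default_rng(0)
        for both in (False, True):
            params = OffParams(both_flanks=both)
            for _ in range(300):
                t = np.sort(rng.uniform(0, 2.0, rng.integers(0, 80)))
                t = np.unique(t)
                _, off = segment_channel(t, params)
                _, off_oracle = oracle_segment_channel(t, params)
                assert intervals_equal(iv_pairs(off), off_oracle)


class TestDetectGlobal:
    def _offs(self, pairs_per_channel):
        return [
            IntervalSet.from_tuples([(s, e, "o") for s, e in pairs])
            for pairs in pairs_per_channel
        ]

    def test_exact_quorum_makes_global_off(self):
        chans = [[(1.0, 1.1)]] * 12 + [[]] * 4
        g_off, _, _ = detect_global(self._offs(chans), 10.0)
        assert intervals_equal(iv_pairs(g_off), [(1.0, 1.1)])

    def test_below_quorum_is_not_off(self):
        chans = [[(1.0, 1.1)]] * 11 + [[]] * 5
        g_off, _, _ = detect_global(self._offs(chans), 10.0)
        assert len(g_off) == 0

    def test_overlong_quorum_run_is_unclassified_not_truncated(self):
        chans = [[(1.0, 1.45)]] * 12 + [[]] * 4
        g_off, _, uncls = detect_global(self._offs(chans), 10.0)
        assert len(g_off) == 0
        assert (1.0, 1.45) in [(s, e) for s, e, _ in uncls]

    def test_channel_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="quorum"):
            detect_global(self._offs([[(0, 1)]] * 8), 10.0)

    def test_global_on_duration_bounds(self):
        # quorum block flanked by sub-quorum runs; only runs in [50, 2000] ms
        # become global ON
        chans = [[(3.0, 3.2)]] * 12 + [[]] * 4
        g_off, g_on, uncls = detect_global(self._offs(chans), 4.0)
        assert intervals_equal(iv_pairs(g_off), [(3.0, 3.2)])
        # [0, 3) is 3 s > 2 s: unclassified; [3.2, 4) is 0.8 s: global ON
        assert intervals_equal(iv_pairs(g_on), [(3.2, 4.0)])
        assert (0.0, 3.0) in [(s, e) for s, e, _ in uncls]

    def test_matches_boundary_sweep_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        params = OffParams()
        for _ in range(100):
            trains = random_spike_instance(rng)
            per_off = [segment_channel(t, params)[1] for t in trains]
            got = detect_global(per_off, 10.0, params)
            want = oracle_detect_global(per_off, 10.0, params)
            for a, b in zip(got, want):
                assert intervals_equal(iv_pairs(a), b)

    def test_raising_quorum_never_increases_off_time(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            trains = random_spike_instance(rng)
            per_off = [segment_channel(t)[1] for t in trains]
            times = []
            for q in (8, 10, 12, 14, 16):
                params = OffParams(quorum=q)
                g_off, _, uncls = detect_global(per_off, 10.0, params)
                # count all quorum time (classified or not) for monotonicity
                quorum_time = g_off.total_duration() + sum(
                    e - s for s, e, _ in uncls
                    if _is_quorum_run(per_off, 0.5 * (s + e), q)
                )
                times.append(quorum_time)
            assert all(a >= b - 1e-12 for a, b in zip(times[:-1], times[1:]))


def _is_quorum_run(per_off, t, quorum):
    n = sum(
        1 for iv in per_off if np.any((iv.starts <= t) & (t < iv.ends))
    )
    return n >= quorum


class TestFallback:
    def test_single_gap(self):
        s = SpikeTrainSet([np.arange(0.0, 0.201, 0.01),
                           np.arange(0.28, 0.296, 0.005)], 0.3, ["a", "b"])
        off = detect_fallback(s)
        assert intervals_equal(iv_pairs(off), [(0.2, 0.28)])

    def test_edges_count_in_fallback_mode(self):
        s = SpikeTrainSet([np.array([0.5])], 1.0, ["a"])
        off = detect_fallback(s)
        assert intervals_equal(iv_pairs(off), [(0.0, 0.5), (0.5, 1.0)])

    def test_empty_recording_is_one_off(self):
        s = SpikeTrainSet([np.empty(0)], 2.0, ["a"])
        off = detect_fallback(s)
        assert intervals_equal(iv_pairs(off), [(0.0, 2.0)])

    def test_poisson_gap_count_matches_expectation(self):
        """Gaps >= 50 ms in a merged Poisson train arrive at ~ T lam e^-lam*tau."""
        rng = np.random.default_rng(3)
        lam, T = 40.0, 600.0  # merged rate: 4 channels at 10 Hz
        counts = []
        for _ in range(5):
            trains = [np.sort(rng.uniform(0, T, rng.poisson(10.0 * T)))
                      for _ in range(4)]
            s = SpikeTrainSet([np.unique(t) for t in trains], T,
                              ["a", "b", "c", "d"])
            counts.append(len(detect_fallback(s)))
        expected = T * lam * np.exp(-lam * 0.05)
        se = np.sqrt(expected)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            trains = random_spike_instance(rng, n_channels=4, duration=5.0)
            s = SpikeTrainSet(trains, 5.0, ["a", "b", "c", "d"])
            got = iv_pairs(detect_fallback(s))
            want = oracle_fallback(trains, 5.0, 0.05)
            assert intervals_equal(got, want)


class TestOffStatistics:
    def test_frequency_arithmetic(self):
        offs = IntervalSet.from_tuples(
            [(10.0 * i + 1.0, 10.0 * i + 1.1, "global_off") for i in range(30)]
        )
        win = IntervalSet.from_arrays([0.0], [600.0], "w")
        freq, dur = off_statistics(offs, win)
        assert freq == pytest.approx(3.0)
        assert dur == pytest.approx(100.0)

    def test_no_events_is_zero_frequency_missing_duration(self):
        win = IntervalSet.from_arrays([0.0], [600.0], "w")
        freq, dur = off_statistics(IntervalSet(), win)
        assert freq == 0.0 and dur is None

    def test_events_outside_windows_excluded(self):
        offs = IntervalSet.from_tuples([(1.0, 1.1, "o"), (50.0, 50.1, "o"),
                                        (9.95, 10.05, "o")])
        win = IntervalSet.from_arrays([0.0], [10.0], "w")
        freq, _ = off_statistics(offs, win)
        # the straddling and outside events do not count
        assert freq == pytest.approx(1.0 / 10.0 * 60.0)

    def test_zero_duration_windows_error(self):
        with pytest.raises(ValueError):
            off_statistics(IntervalSet(), IntervalSet())


class TestParameterRecovery:
    def test_detection_recovers_generator_ground_truth(self, nrem_session):
        """Frequency, mean duration and event hit rate against ground truth
        on a bistable NREM session (jitter 2 ms, participation 0.95)."""
        cfg, spikes, _, truth = nrem_session
        from onoff.offperiods import detect_off_periods

        det = detect_off_periods(spikes)
        win = IntervalSet.from_arrays([0.0], [cfg.session_length], "w")
        f_det, d_det = off_statistics(det["global_off"], win)
        f_true, d_true = off_statistics(truth.population_off, win)
        assert abs(f_det / f_true - 1) < 0.10
        assert abs(d_det / d_true - 1) < 0.10
        assert match_events(det["global_off"], truth.population_off) >= 0.95
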