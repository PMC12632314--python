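"""Domain containers, interval algebra and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from onoff import io as oio
from onoff.intervals import (
    complement,
    intersect,
    merge_union,
    restrict,
    restrict_intervals,
    restrict_spikes,
    restrict_traces,
)
from onoff.types import (
    ContinuousTraces,
    Hypnogram,
    IntervalSet,
    PoseTrack,
    SpikeTrainSet,
    StimulationProtocol,
    StimulationStage,
    VIGILANCE_STATES,
)

# ------------------------------------------------------------ strategies --

finite_time = st.floats(min_value=0.0, max_value=1e5, allow_nan=False,
                        allow_infinity=False)


@st.composite
def interval_sets(draw):
    n = draw(st.integers(0, 12))
    tuples = []
    cursor_by_label: dict[str, float] = {}
    for _ in range(n):
        label = draw(st.sampled_from(["a", "b", "off"]))
        cur = cursor_by_label.get(label, 0.0)
        start = cur + draw(st.floats(0.0, 10.0, allow_nan=False))
        end = start + draw(st.floats(0.001, 10.0, allow_nan=False))
        cursor_by_label[label] = end
        tuples.append((start, end, label))
    return IntervalSet.from_tuples(tuples)


@st.composite
def hypnograms(draw):
    n = draw(st.integers(1, 10))
    cur = 0.0
    states, starts, ends = [], [], []
    for _ in range(n):
        cur += draw(st.floats(0.0, 5.0, allow_nan=False))
        dur = draw(st.floats(0.5, 100.0, allow_nan=False))
        states.append(draw(st.sampled_from(VIGILANCE_STATES)))
        starts.append(cur)
        ends.append(cur + dur)
        cur += dur
    return Hypnogram(states, np.array(starts), np.array(ends))


@st.composite
def spike_sets(draw):
    n_ch = draw(st.integers(1, 4))
    duration = draw(st.floats(1.0, 50.0, allow_nan=False))
    trains = []
    for _ in range(n_ch):
        n = draw(st.integers(0, 30))
        t = np.sort(np.asarray(draw(
            st.lists(st.floats(0.0, duration - 1e-6, allow_nan=False,
                               exclude_max=False), min_size=n, max_size=n)
        )))
        t = np.unique(t)
        trains.append(t)
    ids = [f"ch{i}" for i in range(n_ch)]
    return SpikeTrainSet(trains, duration=duration, channel_ids=ids)


# ------------------------------------------------------------ invariants --

class TestContainers:
    def test_traces_validation(self):
        with pytest.raises(ValueError):
            ContinuousTraces(np.zeros((2, 10)), -1.0, ["a", "b"])
        with pytest.raises(ValueError):
            ContinuousTraces(np.zeros((2, 10)), 100.0, ["a", "a"])
        with pytest.raises(ValueError):
            ContinuousTraces(np.zeros((2, 10)), 100.0, ["a", "b"], kind="oddball")

    def test_spike_trains_must_be_sorted_and_in_range(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([np.array([0.2, 0.1])], 1.0, ["a"])
        with pytest.raises(ValueError):
            SpikeTrainSet([np.array([0.5, 1.5])], 1.0, ["a"])

    def test_interval_overlap_same_label_rejected(self):
        with pytest.raises(ValueError):
            IntervalSet.from_tuples([(0, 2, "x"), (1, 3, "x")])
        # different labels may overlap freely
        IntervalSet.from_tuples([(0, 2, "x"), (1, 3, "y")])

    def test_hypnogram_vocabulary_and_order(self):
        with pytest.raises(ValueError):
            Hypnogram(["Napping"], np.array([0.0]), np.array([1.0]))
        h = Hypnogram(["NREM", "Wake"], np.array([5.0, 0.0]), np.array([8.0, 5.0]))
        assert h.states == ["Wake", "NREM"]  # sorted by start
        assert h.state_at(6.0) == "NREM"
        assert h.state_at(100.0) is None

    def test_protocol_duty_cycle_invariant(self):
        with pytest.raises(ValueError):
            StimulationStage(pulse_rate=10.0, on_time=200.0,
                             stage_duration=60.0, break_duration=10.0)
        StimulationProtocol([StimulationStage(1.0, 180.0, 600.0, 45.0)])


# -------------------------------------------------------------- restrict --

class TestRestrict:
    def test_spikes_half_open_window(self):
        spikes = SpikeTrainSet([np.array([1.0, 2.0, 3.0])], 5.0, ["a"])
        win = IntervalSet.from_arrays([1.5], [2.5], "w")
        out = restrict_spikes(spikes, win)
        assert out.trains[0].tolist() == [2.0]

    def test_interval_clipping_is_set_intersection(self):
        iv = IntervalSet.from_arrays([0.0], [10.0], "x")
        win = IntervalSet.from_arrays([5.0], [20.0], "w")
        out = restrict_intervals(iv, win)
        assert [(s, e) for s, e, _ in out] == [(5.0, 10.0)]

    def test_full_span_is_identity(self):
        spikes = SpikeTrainSet([np.array([0.5, 1.0, 4.0])], 5.0, ["a"])
        win = IntervalSet.from_arrays([0.0], [5.0], "w")
        out = restrict_spikes(spikes, win)
        np.testing.assert_array_equal(out.trains[0], spikes.trains[0])

    def test_traces_restriction_keeps_time_base(self):
        fs = 100.0
        tr = ContinuousTraces(np.arange(1000, dtype=float)[None, :], fs, ["a"])
        win = IntervalSet.from_arrays([2.0], [4.0], "w")
        segs = restrict_traces(tr, win)
        assert len(segs) == 1
        assert segs[0].t0 == pytest.approx(2.0)
        assert segs[0].n_samples == 200
        assert segs[0].data[0, 0] == 200.0

    def test_empty_intersection_is_empty_not_error(self):
        spikes = SpikeTrainSet([np.array([1.0])], 5.0, ["a"])
        win = IntervalSet.from_arrays([3.0], [4.0], "w")
        assert restrict_spikes(spikes, win).total_count() == 0

    @given(interval_sets(), interval_sets())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_union_intersection_measure_identity(self, a, b):
        ua, ub = merge_union(a), merge_union(b)
        union = merge_union(IntervalSet.from_tuples(
            [(s, e, "ua") for s, e, _ in ua] + [(s, e, "ub") for s, e, _ in ub]
        ))
        inter = intersect(ua, ub)
        lhs = union.total_duration() + inter.total_duration()
        rhs = ua.total_duration() + ub.total_duration()
        assert lhs == pytest.approx(rhs, abs=1e-6)

    @given(interval_sets(), interval_sets())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_restrict_is_idempotent(self, x, w):
        if not len(w):
            return
        once = restrict(x, w)
        twice = restrict(once, w)
        assert once == twice

    def test_complement_partitions_span(self):
        iv = IntervalSet.from_tuples([(1, 2, "x"), (4, 6, "x")])
        comp = complement(iv, (0.0, 10.0))
        assert [(s, e) for s, e, _ in comp] == [(0, 1), (2, 4), (6, 10)]
        assert comp.total_duration() + iv.total_duration() == pytest.approx(10.0)


# ------------------------------------------------------------ round-trip --

class TestRoundTrip:
    def test_empty_interval_set(self, tmp_path):
        p = tmp_path / "iv.tsv"
        oio.write_intervals(IntervalSet(), p)
        assert oio.read_intervals(p) == IntervalSet()

    def test_three_bout_hypnogram(self, tmp_path):
        h = Hypnogram(["Wake", "NREM", "REM"], np.array([0.0, 10.0, 100.0]),
                      np.array([10.0, 100.0, 130.0]))
        p = tmp_path / "h.tsv"
        oio.write_hypnogram(h, p)
        assert oio.read_hypnogram(p) == h

    def test_sixteen_channel_spikes(self, tmp_path):
        rng = np.random.default_rng(0)
        trains = [np.unique(rng.uniform(0, 100, 625)) for _ in range(16)]
        s = SpikeTrainSet(trains, 100.0, [f"ch{i:02d}" for i in range(16)])
        p = tmp_path / "s.tsv"
        oio.write_spikes(s, p)
        back = oio.read_spikes(p)
        assert back.channel_ids == s.channel_ids
        assert back.duration == s.duration
        for a, b in zip(back.trains, s.trains):
            np.testing.assert_array_equal(a, b)

    @given(iv=interval_sets())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_interval_roundtrip_property(self, tmp_path_factory, iv):
        p = tmp_path_factory.mktemp("rt") / "iv.tsv"
        oio.write_intervals(iv, p)
        assert oio.read_intervals(p) == iv

    @given(h=hypnograms())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hypnogram_roundtrip_property(self, tmp_path_factory, h):
        p = tmp_path_factory.mktemp("rt") / "h.tsv"
        oio.write_hypnogram(h, p)
        assert oio.read_hypnogram(p) == h

    @given(s=spike_sets())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_spike_roundtrip_property(self, tmp_path_factory, s):
        p = tmp_path_factory.mktemp("rt") / "s.tsv"
        oio.write_spikes(s, p)
        back = oio.read_spikes(p)
        assert back.duration == s.duration
        for a, b in zip(back.trains, s.trains):
            np.testing.assert_array_equal(a, b)

    def test_traces_roundtrip_binary_sidecar(self, tmp_path):
        rng = np.random.default_rng(1)
        tr = ContinuousTraces(rng.standard_normal((3, 500)), 400.0,
                              ["a", "b", "c"], t0=2.5, kind="lfp")
        oio.write_traces(tr, tmp_path / "x")
        back = oio.read_traces(tmp_path / "x")
        np.testing.assert_array_equal(back.data, tr.data)
        assert back.sample_rate == tr.sample_rate
        assert back.t0 == tr.t0 and back.kind == tr.kind

    def test_pose_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        track = PoseTrack(rng.uniform(0, 640, (20, 3, 2)), 1.0,
                          ["nose", "center", "tail"])
        oio.write_pose(track, tmp_path / "p.tsv")
        back = oio.read_pose(tmp_path / "p.tsv")
        np.testing.assert_array_equal(back.positions, track.positions)
        assert back.node_names == track.node_names

    def test_protocol_roundtrip(self, tmp_path):
        from onoff.synth import default_induction_protocol

        proto = default_induction_protocol()
        oio.write_protocol(proto, tmp_path / "p.json")
        back = oio.read_protocol(tmp_path / "p.json")
        assert back == proto

    def test_malformed_file_reports_parse_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("state\tstart_s\n")  # missing end_s column
        with pytest.raises(oio.ParseError, match="end_s"):
            oio.read_hypnogram(p)
        p2 = tmp_path / "bad2.tsv"
        p2.write_text("state\tstart_s\tend_s\nNREM\tzero\t1.0\n")
        with pytest.raises(oio.ParseError):
            oio.read_hypnogram(p2)

    def test_invariant_violation_on_read_is_validation_error(self, tmp_path):
        p = tmp_path / "bad3.tsv"
        p.write_text("label\tstart_s\tend_s\nx\t5.0\t1.0\n")
        with pytest.raises(oio.ParseError):
            oio.read_intervals(p)
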