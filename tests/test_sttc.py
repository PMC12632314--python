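"""STTC formula correctness, symmetry, bounds, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_sttc
from onoff.config import SttcParams
from onoff.sttc import condition_difference, fisher_z, sttc_condition, sttc_pair
from onoff.types import IntervalSet, SpikeTrainSet


def _train(*times):
    return np.asarray(times, dtype=np.float64)


class TestSttcPair:
    def test_identical_trains_exactly_one(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 10, 50))
        assert sttc_pair(t, t, 10.0) == pytest.approx(1.0, abs=1e-12)

    def test_two_spike_hand_example(self):
        """A={100 ms}, B={103 ms}, 1 s window: T=1, P=0.010, STTC=1."""
        r = sttc_pair(_train(0.100), _train(0.103), 1.0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = np.sort(rng.uniform(0, 5, rng.integers(1, 40)))
            b = np.sort(rng.uniform(0, 5, rng.integers(1, 40)))
            assert sttc_pair(a, b, 5.0) == sttc_pair(b, a, 5.0)

    def test_empty_train_is_missing_not_zero(self):
        assert np.isnan(sttc_pair(_train(), _train(0.5), 1.0))
        assert np.isnan(sttc_pair(_train(0.5), _train(), 1.0))

    def test_independent_poisson_null_is_centred_on_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(100):
            a = np.sort(rng.uniform(0, 300, rng.poisson(5 * 300)))
            b = np.sort(rng.uniform(0, 300, rng.poisson(5 * 300)))
            vals.append(sttc_pair(a, b, 300.0))
        assert abs(np.mean(vals)) < 0.02

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        for formula in ("as_printed", "cutts_eglen"):
            params = SttcParams(formula=formula)
            for _ in range(100):
                a = np.sort(rng.uniform(0, 2, rng.integers(1, 30)))
                b = np.sort(rng.uniform(0, 2, rng.integers(1, 30)))
                got = sttc_pair(a, b, 2.0, params)
                want = oracle_sttc(a, b, 0.0, 2.0, params.dt, formula)
                assert got == pytest.approx(want, abs=1e-9)

    def test_formulas_differ_for_asymmetric_rates(self):
        """The printed own-train pairing and the cross-paired original give
        different values once the two trains have unequal tiling."""
        rng = np.random.default_rng(4)
        a = np.sort(rng.uniform(0, 10, 200))
        b = np.sort(rng.uniform(0, 10, 10))
        printed = sttc_pair(a, b, 10.0, SttcParams(formula="as_printed"))
        original = sttc_pair(a, b, 10.0, SttcParams(formula="cutts_eglen"))
        assert printed != pytest.approx(original, abs=1e-6)

    def test_multi_interval_window_tiling_clipped(self):
        # spike near an epoch edge: its tile is clipped at the boundary
        win = IntervalSet.from_tuples([(0.0, 1.0, "w"), (2.0, 3.0, "w")])
        a = _train(0.999)
        b = _train(0.998)
        r = sttc_pair(a, b, win)
        # P = clipped tile (6 ms) / 2 s window; T = 1 for both
        assert r == pytest.approx(1.0, abs=1e-12)

    @given(
        a=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=60),
        b=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=60),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_bounded_in_minus_one_one(self, a, b):
        a = np.unique(np.asarray(a))
        b = np.unique(np.asarray(b))
        r = sttc_pair(a, b, 10.0 + 1e-6)
        if np.isfinite(r):
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    def test_rate_robustness_under_thinning(self):
        """Thinning two trains correlated through shared ON/OFF rate
        modulation by 50% moves the mean STTC by < 0.05: the tiling
        correction absorbs the rate change."""
        from onoff.synth import GeneratorConfig, simulate_session
        from onoff.types import Hypnogram

        rng = np.random.default_rng(5)
        shifts = []
        for seed in range(50):
            cfg = GeneratorConfig(seed=seed, session_length=60.0,
                                  state_schedule=Hypnogram(["NREM"], [0.0], [60.0]),
                                  n_channels=2, channel_jitter_sd_ms=2.0,
                                  make_lfp=False, make_emg=False)
            spikes, _, _, _ = simulate_session(cfg)
            a, b = spikes.trains
            full = sttc_pair(a, b, 60.0)
            at = a[rng.random(a.size) < 0.5]
            bt = b[rng.random(b.size) < 0.5]
            thinned = sttc_pair(np.sort(at), np.sort(bt), 60.0)
            shifts.append(thinned - full)
        assert abs(np.mean(shifts)) < 0.05


class TestSttcCondition:
    def test_single_bout_equals_pair_value(self):
        rng = np.random.default_rng(6)
        a = np.sort(rng.uniform(0, 10, 60))
        b = np.sort(rng.uniform(0, 10, 60))
        spikes = SpikeTrainSet([a, b], 10.0, ["x", "y"])
        win = IntervalSet.from_arrays([0.0], [10.0], "c")
        mat = sttc_condition(spikes, win)
        assert mat.values[0, 1] == pytest.approx(sttc_pair(a, b, win), abs=1e-12)

    def test_epochs_average_in_coefficient_space(self):
        # construct two bouts with known pair values, average must be their mean
        rng = np.random.default_rng(7)
        a1 = np.sort(rng.uniform(0, 10, 50))
        b1 = np.sort(rng.uniform(0, 10, 50))
        a2 = np.sort(rng.uniform(20, 30, 50))
        b2 = np.sort(rng.uniform(20, 30, 50))
        spikes = SpikeTrainSet([np.concatenate([a1, a2]),
                                np.concatenate([b1, b2])], 30.0, ["x", "y"])
        bouts = IntervalSet.from_tuples([(0.0, 10.0, "c"), (20.0, 30.0, "c")])
        w1 = IntervalSet.from_arrays([0.0], [10.0], "c")
        w2 = IntervalSet.from_arrays([20.0], [30.0], "c")
        expected = 0.5 * (sttc_pair(a1, b1, w1) + sttc_pair(a2, b2, w2))
        mat = sttc_condition(spikes, bouts)
        assert mat.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_shared_train_gives_all_ones(self):
        t = np.sort(np.random.default_rng(8).uniform(0, 10, 80))
        spikes = SpikeTrainSet([t.copy() for _ in range(4)], 10.0,
                               ["a", "b", "c", "d"])
        mat = sttc_condition(spikes, IntervalSet.from_arrays([0.0], [10.0], "c"))
        np.testing.assert_allclose(mat.values, 1.0, atol=1e-12)

    def test_silent_channel_rows_missing(self):
        t = np.sort(np.random.default_rng(9).uniform(0, 10, 40))
        spikes = SpikeTrainSet([t, np.empty(0)], 10.0, ["a", "b"])
        mat = sttc_condition(spikes, IntervalSet.from_arrays([0.0], [10.0], "c"))
        assert np.isnan(mat.values[0, 1])
        assert mat.values[0, 0] == 1.0 and np.isnan(mat.values[1, 1])

    def test_short_bouts_skipped(self):
        t = np.sort(np.random.default_rng(10).uniform(0, 10, 40))
        spikes = SpikeTrainSet([t, t], 10.0, ["a", "b"])
        bouts = IntervalSet.from_tuples([(0.0, 0.005, "c")])
        with pytest.raises(ValueError, match="minimum"):
            sttc_condition(spikes, bouts)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_unit_r_clips_to_known_value(self):
        # atanh(1 - 1e-6) = 0.5 ln((2 - 1e-6)/1e-6)
        assert fisher_z(1.0) == pytest.approx(7.254329, abs=1e-5)
        assert fisher_z(-1.0) == pytest.approx(-7.254329, abs=1e-5)

    def test_condition_difference_zero_for_equal_matrices(self):
        t = np.sort(np.random.default_rng(11).uniform(0, 10, 60))
        spikes = SpikeTrainSet([t, np.sort(t + 0.001)], 10.0, ["a", "b"])
        mat = sttc_condition(spikes, IntervalSet.from_arrays([0.0], [10.0], "c"))
        diff = condition_difference(mat, mat)
        np.testing.assert_allclose(diff[np.isfinite(diff)], 0.0)

    def test_condition_difference_requires_alignment(self):
        t = np.sort(np.random.default_rng(12).uniform(0, 10, 60))
        s1 = SpikeTrainSet([t, t], 10.0, ["a", "b"])
        s2 = SpikeTrainSet([t, t], 10.0, ["a", "c"])
        win = IntervalSet.from_arrays([0.0], [10.0], "c")
        m1, m2 = sttc_condition(s1, win), sttc_condition(s2, win)
        with pytest.raises(ValueError, match="aligned"):
            condition_difference(m1, m2)


class TestGeneratorSynchrony:
    def test_sttc_decreases_with_channel_jitter(self):
        """The generator's jitter dial moves population synchrony in the
        expected direction (paired seeds, small sessions)."""
        from onoff.synth import GeneratorConfig, simulate_session
        from onoff.types import Hypnogram

        hyp = Hypnogram(["NREM"], [0.0], [120.0])
        means = []
        for jit in (1.0, 20.0):
            vals = []
            for seed in range(3):
                cfg = GeneratorConfig(seed=seed, session_length=120.0,
                                      state_schedule=hyp, n_channels=6,
                                      channel_jitter_sd_ms=jit,
                                      make_lfp=False, make_emg=False)
                spikes, _, _, _ = simulate_session(cfg)
                mat = sttc_condition(
                    spikes, IntervalSet.from_arrays([0.0], [120.0], "c"))
                vals.append(mat.offdiag_mean())
            means.append(np.mean(vals))
        assert means[0] > means[1]
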