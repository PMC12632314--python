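"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's optimized code paths:
pure-Python scanners for ON/OFF segmentation and quorum detection, an
O(n^2) all-pairs STTC, and closed-form expectations.  They exist so the
implementation can be checked against something that cannot share its
bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

from onoff.config import OffParams
from onoff.types import IntervalSet


# ---------------------------------------------------------------- oracles --

def oracle_segment_channel(train, params: OffParams):
    """Brute-force single-channel ON/OFF scanner (independent of the
    vectorized implementation): explicit run building and flank checks."""
    t = list(map(float, train))
    if not t:
        return [], []
    runs = [[t[0], t[0]]]
    for a, b in zip(t[:-1], t[1:]):
        if b - a >= params.max_isi_in_on:
            runs.append([b, b])
        else:
            runs[-1][1] = b
    ons = [(s, e) for s, e in runs]
    offs = []
    for (s1, e1), (s2, e2) in zip(runs[:-1], runs[1:]):
        gap = s2 - e1
        if gap < params.min_off:
            continue
        left = (e1 - s1) >= params.min_flank_on
        right = (e2 - s2) >= params.min_flank_on
        ok = (left and right) if params.both_flanks else (left or right)
        if ok:
            offs.append((e1, s2))
    return ons, offs


def oracle_detect_global(per_channel_off, duration, params: OffParams):
    """Event-boundary sweep recomputing n(t) from scratch per segment.

    For every segment between consecutive boundaries, count channels whose
    OFF list contains the segment midpoint, then merge and classify runs.
    """
    bounds = {0.0, float(duration)}
    chans = []
    for iv in per_channel_off:
        pairs = [(float(s), float(e)) for s, e, _ in iv]
        chans.append(pairs)
        for s, e in pairs:
            bounds.add(s)
            bounds.add(e)
    bounds = sorted(b for b in bounds if 0.0 <= b <= duration)
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (s + e)
        n = sum(
            1 for pairs in chans if any(a <= mid < b for a, b in pairs)
        )
        quorum = n >= params.quorum
        if segments and segments[-1][2] == quorum:
            segments[-1] = (segments[-1][0], e, quorum)
        else:
            segments.append((s, e, quorum))
    g_off, g_on, uncls = [], [], []
    for s, e, quorum in segments:
        d = e - s
        if quorum:
            lo, hi = params.global_off_bounds
            (g_off if lo <= d <= hi else uncls).append((s, e))
        else:
            lo, hi = params.global_on_bounds
            (g_on if lo <= d <= hi else uncls).append((s, e))
    return g_off, g_on, uncls


def oracle_fallback(trains, duration, min_off):
    merged = sorted(float(x) for t in trains for x in t)
    edges = [0.0] + merged + [float(duration)]
    return [
        (a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a >= min_off
    ]


def oracle_sttc(a, b, t_start, t_stop, dt, formula="as_printed"):
    """O(n^2) proximity T plus scan-line union P, straight off the formula."""
    a = [x for x in map(float, a) if t_start <= x < t_stop]
    b = [x for x in map(float, b) if t_start <= x < t_stop]
    if not a or not b:
        return float("nan")

    def t_frac(xs, ys):
        hit = 0
        for x in xs:
            if any(abs(x - y) <= dt for y in ys):
                hit += 1
        return hit / len(xs)

    def p_frac(xs):
        ivs = sorted((max(x - dt, t_start), min(x + dt, t_stop)) for x in xs)
        total = 0.0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total / (t_stop - t_start)

    ta, tb = t_frac(a, b), t_frac(b, a)
    pa, pb = p_frac(a), p_frac(b)
    if formula == "as_printed":
        pairs = ((ta, pa), (tb, pb))
    else:
        pairs = ((ta, pb), (tb, pa))
    return 0.5 * sum((t - p) / (1.0 - t * p) for t, p in pairs)


def random_spike_instance(rng, n_channels=16, duration=10.0):
    """A random small multichannel spike set exercising sparse, bursty and
    silent channels alike."""
    trains = []
    for _ in range(n_channels):
        style = rng.integers(0, 4)
        if style == 0:
            n = 0
        elif style == 1:
            n = rng.integers(1, 6)
        elif style == 2:
            n = rng.integers(5, 60)
        else:
            n = rng.integers(60, 400)
        t = np.sort(rng.uniform(0, duration, n))
        t = t[np.insert(np.diff(t) > 1e-4, 0, True)] if t.size else t
        trains.append(t)
    return trains


def intervals_equal(pairs_a, pairs_b, tol=1e-9):
    if len(pairs_a) != len(pairs_b):
        return False
    return all(
        abs(s1 - s2) <= tol and abs(e1 - e2) <= tol
        for (s1, e1), (s2, e2) in zip(pairs_a, pairs_b)
    )


def iv_pairs(iv: IntervalSet):
    return [(float(s), float(e)) for s, e, _ in iv]


# --------------------------------------------------------------- fixtures --

@pytest.fixture(scope="session")
def nrem_session():
    """One deterministic NREM-only session shared by recovery-style tests."""
    from onoff.synth import GeneratorConfig, simulate_session
    from onoff.types import Hypnogram

    cfg = GeneratorConfig(
        seed=7,
        session_length=300.0,
        state_schedule=Hypnogram(["NREM"], [0.0], [300.0]),
        make_emg=False,
    )
    spikes, lfp, _, truth = simulate_session(cfg)
    return cfg, spikes, lfp, truth
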