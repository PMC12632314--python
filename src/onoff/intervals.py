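"""Half-open interval arithmetic: union, intersection, restriction.

These primitives back every per-condition computation: restricting spikes
or traces to NREM bouts, clipping laser epochs to conditions, measuring the
time base of synchrony coefficients.  All operations respect the half-open
``[start, end)`` convention, so a spike at exactly ``end`` is excluded.
"""

from __future__ import annotations

import numpy as np

from .types import ContinuousTraces, IntervalSet, SpikeTrainSet

__all__ = [
    "merge_union",
    "intersect",
    "intersect_windows",
    "complement",
    "restrict_intervals",
    "restrict_spikes",
    "restrict_traces",
    "restrict",
]


def _pairs(iv: IntervalSet) -> np.ndarray:
    """(n, 2) array of start/end pairs ignoring labels."""
    return np.column_stack([iv.starts, iv.ends]) if len(iv) else np.empty((0, 2))


def merge_union(iv: IntervalSet, label: str = "union") -> IntervalSet:
    """Union of all intervals (labels ignored), merged into disjoint runs.

    Touching intervals ``[a, b)`` and ``[b, c)`` merge into ``[a, c)``.
    """
    p = _pairs(iv)
    p = p[p[:, 1] > p[:, 0]]  # drop zero-width
    if not p.size:
        return IntervalSet()
    p = p[np.argsort(p[:, 0], kind="stable")]
    out = []
    cur_s, cur_e = p[0]
    for s, e in p[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e, label))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e, label))
    return IntervalSet.from_tuples(out)


def intersect(a: IntervalSet, b: IntervalSet, label: str = "intersection") -> IntervalSet:
    """Intersection of the unions of two interval sets."""
    ua, ub = merge_union(a), merge_union(b)
    out = []
    i = j = 0
    while i < len(ua) and j < len(ub):
        s = max(ua.starts[i], ub.starts[j])
        e = min(ua.ends[i], ub.ends[j])
        if s < e:
            out.append((s, e, label))
        if ua.ends[i] <= ub.ends[j]:
            i += 1
        else:
            j += 1
    return IntervalSet.from_tuples(out)


def intersect_windows(iv: IntervalSet, windows: IntervalSet) -> IntervalSet:
    """Clip each labelled interval of ``iv`` to the union of ``windows``.

    Unlike :func:`intersect` this preserves the original labels, so it is
    the right tool for restricting labelled events (OFF periods, laser
    pulses) to condition windows.
    """
    win = merge_union(windows)
    if not len(win) or not len(iv):
        return IntervalSet()
    out = []
    for s, e, l in iv:
        j0 = int(np.searchsorted(win.ends, s, side="right"))
        for j in range(j0, len(win)):
            if win.starts[j] >= e and e > s:
                break
            cs = max(s, win.starts[j])
            ce = min(e, win.ends[j])
            if cs < ce or (s == e and win.starts[j] <= s < win.ends[j]):
                out.append((cs, ce, l))
    return IntervalSet.from_tuples(out)


def complement(iv: IntervalSet, span: tuple[float, float], label: str = "complement") -> IntervalSet:
    """Gaps of the union of ``iv`` within ``[span[0], span[1])``."""
    lo, hi = span
    u = intersect(merge_union(iv), IntervalSet.from_arrays([lo], [hi]))
    out = []
    cur = lo
    for s, e, _ in u:
        if s > cur:
            out.append((cur, s, label))
        cur = e
    if cur < hi:
        out.append((cur, hi, label))
    return IntervalSet.from_tuples(out)


def restrict_intervals(iv: IntervalSet, windows: IntervalSet) -> IntervalSet:
    """Restrict labelled intervals to windows (alias of clipping)."""
    return intersect_windows(iv, windows)


def restrict_spikes(spikes: SpikeTrainSet, windows: IntervalSet) -> SpikeTrainSet:
    """Keep only spikes inside the union of windows; duration becomes the
    retained measure.  Spike times are left on the original time base."""
    win = merge_union(windows)
    if not len(win):
        raise ValueError("windows must be non-empty")
    trains = []
    for t in spikes.trains:
        if not t.size:
            trains.append(t)
            continue
        keep = np.zeros(t.size, dtype=bool)
        lo = np.searchsorted(t, win.starts, side="left")
        hi = np.searchsorted(t, win.ends, side="left")
        for a, b in zip(lo, hi):
            keep[a:b] = True
        trains.append(t[keep])
    return SpikeTrainSet(trains, duration=spikes.duration, channel_ids=list(spikes.channel_ids))


def restrict_traces(traces: ContinuousTraces, windows: IntervalSet) -> list[ContinuousTraces]:
    """Cut a continuous recording into one segment per window.

    Each returned segment keeps its own ``t0`` so sample times remain on the
    session time base.  Windows with no overlap are dropped.
    """
    win = merge_union(windows)
    out = []
    t0, fs, n = traces.t0, traces.sample_rate, traces.n_samples
    for s, e, _ in win:
        i0 = max(0, int(np.ceil((s - t0) * fs - 1e-9)))
        i1 = min(n, int(np.ceil((e - t0) * fs - 1e-9)))
        if i1 > i0:
            out.append(
                ContinuousTraces(
                    traces.data[:, i0:i1],
                    fs,
                    list(traces.channel_ids),
                    t0=t0 + i0 / fs,
                    kind=traces.kind,
                )
            )
    return out


def restrict(obj, windows: IntervalSet):
    """Dispatch restriction by object type (spikes, intervals or traces)."""
    if isinstance(obj, SpikeTrainSet):
        return restrict_spikes(obj, windows)
    if isinstance(obj, IntervalSet):
        return restrict_intervals(obj, windows)
    if isinstance(obj, ContinuousTraces):
        return restrict_traces(obj, windows)
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")
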