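"""Single-channel and population-level ON/OFF period segmentation.

Single-channel rule: an ON period is a run of spikes whose every interspike
interval is below 50 ms; a candidate OFF is an inter-run gap of at least
50 ms, accepted when a flanking ON run lasts at least 30 ms (one side by
default, both sides optionally).  Global rule: with 16 channels, a global
OFF is a maximal stretch where at least 12 channels are simultaneously in
a single-channel OFF, lasting 50-400 ms; a global ON is a maximal
sub-quorum stretch lasting 50-2000 ms; stretches violating their duration
bound are left unclassified rather than truncated.  A fallback definition
(for very low MUA) takes every gap of at least 50 ms in the merged
all-channel spike train.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import OffParams
from .types import IntervalSet, SpikeTrainSet

log = logging.getLogger(__name__)

__all__ = [
    "segment_channel",
    "detect_global",
    "detect_fallback",
    "detect_off_periods",
    "off_statistics",
    "match_events",
]


def segment_channel(
    train: np.ndarray, params: OffParams | None = None, label: str = ""
) -> tuple[IntervalSet, IntervalSet]:
    """Split one spike train into ON runs and accepted OFF periods.

    ON runs span first-to-last spike of maximal runs with all internal ISIs
    below ``max_isi_in_on`` (zero-width for single spikes).  Candidate OFFs
    are inter-run gaps >= ``min_off``; a candidate is accepted when at
    least one adjacent run lasts >= ``min_flank_on`` (both runs with
    ``both_flanks``), which forbids an OFF surrounded by two single-spike
    runs.  Stretches before the first and after the last spike are never
    OFF periods here (no flanking ON exists).
    """
    params = params or OffParams()
    t = np.asarray(train, dtype=np.float64)
    on_label = f"single_on:{label}" if label else "single_on"
    off_label = f"single_off:{label}" if label else "single_off"
    if t.size == 0:
        return IntervalSet(), IntervalSet()
    isi = np.diff(t)
    breaks = np.flatnonzero(isi >= params.max_isi_in_on)
    run_start = np.concatenate([[0], breaks + 1])
    run_end = np.concatenate([breaks, [t.size - 1]])  # inclusive indices
    on_s, on_e = t[run_start], t[run_end]
    on = IntervalSet(on_s, on_e, [on_label] * on_s.size)

    run_len = on_e - on_s
    offs = []
    for i in range(len(run_len) - 1):
        gap_s, gap_e = on_e[i], on_s[i + 1]
        if gap_e - gap_s < params.min_off:
            continue
        left_ok = run_len[i] >= params.min_flank_on
        right_ok = run_len[i + 1] >= params.min_flank_on
        ok = (left_ok and right_ok) if params.both_flanks else (left_ok or right_ok)
        if ok:
            offs.append((gap_s, gap_e, off_label))
    return on, IntervalSet.from_tuples(offs)


def detect_global(
    per_channel_off: list[IntervalSet],
    duration: float,
    params: OffParams | None = None,
) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Quorum detection of global OFF / ON periods.

    Builds the step function n(t) = number of channels currently inside a
    single-channel OFF, takes maximal stretches with n >= quorum (candidate
    OFF) or n < quorum (candidate ON), and keeps those whose duration falls
    inside the configured bounds; out-of-bounds stretches are returned as
    ``unclassified``.
    """
    params = params or OffParams()
    if len(per_channel_off) != params.n_channels:
        raise ValueError(
            f"{len(per_channel_off)} channels given but params.n_channels is "
            f"{params.n_channels}; set an explicit quorum/n_channels instead "
            "of relying on 12-of-16 rescaling"
        )
    events = []
    for iv in per_channel_off:
        for s, e, _ in iv:
            if e > s:
                events.append((s, +1))
                events.append((e, -1))
    bounds_off = params.global_off_bounds
    bounds_on = params.global_on_bounds

    # boundary sweep: n(t) is constant between consecutive event times
    times = sorted({0.0, duration} | {t for t, _ in events})
    deltas = {}
    for t_ev, d in events:
        deltas[t_ev] = deltas.get(t_ev, 0) + d

    seg_start = times[0]
    n = 0
    state = n >= params.quorum
    runs = []  # (start, end, was_quorum)
    for t_ev in times[1:]:
        n += deltas.get(seg_start, 0) if seg_start in deltas else 0
        # recompute state for segment [seg_start, t_ev)
        new_state = n >= params.quorum
        if runs and runs[-1][2] == new_state and runs[-1][1] == seg_start:
            runs[-1] = (runs[-1][0], t_ev, new_state)
        else:
            runs.append((seg_start, t_ev, new_state))
        seg_start = t_ev

    g_off, g_on, uncls = [], [], []
    for s, e, quorum in runs:
        d = e - s
        if quorum:
            if bounds_off[0] <= d <= bounds_off[1]:
                g_off.append((s, e, "global_off"))
            else:
                uncls.append((s, e, "unclassified"))
        else:
            if bounds_on[0] <= d <= bounds_on[1]:
                g_on.append((s, e, "global_on"))
            else:
                uncls.append((s, e, "unclassified"))
    return (
        IntervalSet.from_tuples(g_off),
        IntervalSet.from_tuples(g_on),
        IntervalSet.from_tuples(uncls),
    )


def detect_fallback(spikes: SpikeTrainSet, params: OffParams | None = None) -> IntervalSet:
    """Low-MUA fallback: gaps >= min_off in the merged all-channel train.

    No flanking or upper-duration condition applies, and silent stretches
    touching the recording edges count (an empty recording of length
    >= min_off is one OFF period covering it entirely).
    """
    params = params or OffParams()
    merged = spikes.merged()
    edges = np.concatenate([[0.0], merged, [spikes.duration]])
    gaps_s = edges[:-1]
    gaps_e = edges[1:]
    keep = (gaps_e - gaps_s) >= params.min_off
    return IntervalSet.from_arrays(gaps_s[keep], gaps_e[keep], "global_off")


def detect_off_periods(
    spikes: SpikeTrainSet, params: OffParams | None = None
) -> dict[str, IntervalSet | list[IntervalSet]]:
    """Full OFF detection on a spike-train set, per the configured mode.

    Returns a dict with keys ``single_off`` (list per channel),
    ``global_off``, ``global_on``, ``unclassified``.  In fallback mode only
    ``global_off`` is populated.
    """
    params = params or OffParams()
    if params.mode == "fallback":
        return {
            "single_off": [],
            "global_off": detect_fallback(spikes, params),
            "global_on": IntervalSet(),
            "unclassified": IntervalSet(),
        }
    single = []
    for cid, train in zip(spikes.channel_ids, spikes.trains):
        _, off = segment_channel(train, params, label=cid)
        single.append(off)
    g_off, g_on, uncls = detect_global(single, spikes.duration, params)
    return {
        "single_off": single,
        "global_off": g_off,
        "global_on": g_on,
        "unclassified": uncls,
    }


def off_statistics(
    global_off: IntervalSet, condition_windows: IntervalSet
) -> tuple[float, float | None]:
    """OFF frequency (events/min) and mean duration (ms) within windows.

    Only events falling fully inside the union of windows are counted.
    With no events the frequency is 0 and the duration is None (missing).
    """
    if not len(condition_windows):
        raise ValueError("condition windows must be non-empty")
    total = condition_windows.total_duration()
    if total <= 0:
        raise ValueError("condition windows have zero duration")
    from .intervals import merge_union

    win = merge_union(condition_windows)
    durs = []
    for s, e, _ in global_off:
        j = np.searchsorted(win.starts, s, side="right") - 1
        if j >= 0 and win.starts[j] <= s and e <= win.ends[j]:
            durs.append(e - s)
    freq = len(durs) / total * 60.0
    mean_ms = float(np.mean(durs) * 1000.0) if durs else None
    return freq, mean_ms


def match_events(
    detected: IntervalSet, truth: IntervalSet, tolerance: float = 0.025
) -> float:
    """Fraction of truth events whose midpoint is matched by a detected
    midpoint within ``tolerance`` seconds (greedy one-to-one matching)."""
    if not len(truth):
        return float("nan")
    det = np.sort(detected.midpoints())
    hits = 0
    used = np.zeros(det.size, dtype=bool)
    for m in truth.midpoints():
        j = np.searchsorted(det, m)
        for k in (j - 1, j):
            if 0 <= k < det.size and not used[k] and abs(det[k] - m) <= tolerance:
                used[k] = True
                hits += 1
                break
    return hits / len(truth)
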