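"""OFF-locked LFP averages and synchrony-sensitive waveform metrics.

For a condition's OFF periods, LFP snippets are extracted per channel and
aligned to the OFF start, end or midpoint; the event-locked average is the
substrate for three metrics: the maximal first derivative within +/-10
samples of the OFF start (initiation slope), the same at the OFF end
(termination slope), and the peak field potential within +/-20 samples of
the OFF midpoint.  Derivatives are taken after Savitzky-Golay smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import SavgolParams
from .types import ContinuousTraces, IntervalSet

log = logging.getLogger(__name__)

__all__ = [
    "EventLockedAverage",
    "event_locked_average",
    "initiation_slope",
    "termination_slope",
    "off_peak_amplitude",
]

ALIGNMENTS = ("off_start", "off_end", "off_midpoint")


@dataclass
class EventLockedAverage:
    """Mean and SEM across events, per channel and lag sample."""

    lags: np.ndarray          # samples relative to the alignment point
    mean: np.ndarray          # (channels, lags)
    sem: np.ndarray           # (channels, lags)
    n_events: int
    alignment: str
    sample_rate: float
    channel_ids: list[str]

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"alignment must be one of {ALIGNMENTS}")


def event_locked_average(
    lfp: ContinuousTraces,
    events: IntervalSet,
    alignment: str = "off_start",
    half_width: int | None = None,
    max_events: int | None = None,
) -> EventLockedAverage:
    """Average LFP snippets aligned to an event landmark.

    ``half_width`` is in samples (default: 1 s worth, covering the longest
    global OFF plus flanks).  Events whose snippet would cross a recording
    edge are dropped; ``max_events`` caps the analysis to the first N
    events (event-count subsetting for fair condition comparisons).
    """
    if alignment not in ALIGNMENTS:
        raise ValueError(f"alignment must be one of {ALIGNMENTS}")
    if not len(events):
        raise ValueError("events must be non-empty")
    fs = lfp.sample_rate
    if half_width is None:
        half_width = int(round(fs))
    if alignment == "off_start":
        anchors = events.starts
    elif alignment == "off_end":
        anchors = events.ends
    else:
        anchors = events.midpoints()
    if max_events is not None:
        anchors = anchors[:max_events]
    centers = np.round((anchors - lfp.t0) * fs).astype(np.int64)
    ok = (centers - half_width >= 0) & (centers + half_width < lfp.n_samples)
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("all events fall too close to the recording edges")
    lags = np.arange(-half_width, half_width + 1)
    idx = centers[:, None] + lags[None, :]
    snippets = lfp.data[:, idx]                      # (channels, events, lags)
    mean = snippets.mean(axis=1)
    if centers.size > 1:
        sem = snippets.std(axis=1, ddof=1) / np.sqrt(centers.size)
    else:
        sem = np.zeros_like(mean)
    return EventLockedAverage(lags=lags, mean=mean, sem=sem,
                              n_events=int(centers.size), alignment=alignment,
                              sample_rate=fs, channel_ids=list(lfp.channel_ids))


def _max_derivative(avg: EventLockedAverage, savgol: SavgolParams,
                    lag_window: int) -> np.ndarray:
    if savgol.window > avg.mean.shape[1]:
        raise ValueError("Savitzky-Golay window exceeds the snippet length")
    lo = np.searchsorted(avg.lags, -lag_window)
    hi = np.searchsorted(avg.lags, lag_window, side="right")
    if avg.lags[0] > -lag_window or avg.lags[-1] < lag_window:
        raise ValueError(f"snippet must cover +/-{lag_window} samples around lag 0")
    smooth = savgol_filter(avg.mean, savgol.window, savgol.polyorder, axis=1)
    deriv = np.diff(smooth, axis=1) * avg.sample_rate
    # diff sample i sits between lags i and i+1; the window [-w, +w] in lag
    # units maps to diff indices [lo, hi-1)
    return deriv[:, lo:hi - 1].max(axis=1)


def initiation_slope(
    avg: EventLockedAverage,
    savgol: SavgolParams | None = None,
    lag_window: int = 10,
) -> np.ndarray:
    """Maximal smoothed first derivative near the OFF start (per channel, mV/s).

    Exact on polynomials up to the Savitzky-Golay order, so a linear ramp of
    slope m returns m.
    """
    if avg.alignment != "off_start":
        raise ValueError("initiation slope needs an average aligned to off_start")
    return _max_derivative(avg, savgol or SavgolParams(), lag_window)


def termination_slope(
    avg: EventLockedAverage,
    savgol: SavgolParams | None = None,
    lag_window: int = 10,
) -> np.ndarray:
    """Maximal smoothed first derivative near the OFF end (per channel, mV/s)."""
    if avg.alignment != "off_end":
        raise ValueError("termination slope needs an average aligned to off_end")
    return _max_derivative(avg, savgol or SavgolParams(), lag_window)


def off_peak_amplitude(
    avg: EventLockedAverage,
    lag_window: int = 20,
    polarity: str = "positive",
) -> np.ndarray:
    """Peak of the average waveform within +/-20 samples of the OFF midpoint.

    For positive-going slow waves this is the signed maximum; for
    negative-going (ACR-like) recordings set ``polarity="negative"`` to
    take the signed minimum (the trough depth, returned with its sign).
    """
    if avg.alignment != "off_midpoint":
        raise ValueError("peak amplitude needs an average aligned to off_midpoint")
    if avg.lags[0] > -lag_window or avg.lags[-1] < lag_window:
        raise ValueError(f"snippet must cover +/-{lag_window} samples around lag 0")
    lo = np.searchsorted(avg.lags, -lag_window)
    hi = np.searchsorted(avg.lags, lag_window, side="right")
    seg = avg.mean[:, lo:hi]
    if polarity == "positive":
        return seg.max(axis=1)
    if polarity == "negative":
        return seg.min(axis=1)
    raise ValueError("polarity must be 'positive' or 'negative'")
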