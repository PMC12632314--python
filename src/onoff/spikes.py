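"""Wideband preprocessing, MUA spike detection and firing rates.

The chain is: zero-phase FIR band-pass (300-12000 Hz) -> per-sample common
median reference across channels -> robust noise estimate (MAD) -> local
extrema beyond ``k * sigma`` in the configured polarity, with a short
refractory window suppressing duplicate peaks of one waveform.  A separate
path low-passes and decimates the wideband signal to produce the LFP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import SpikeDetectionParams
from .types import ContinuousTraces, SpikeTrainSet

log = logging.getLogger(__name__)

__all__ = [
    "NoiseEstimate",
    "FiringRateSeries",
    "preprocess_wideband",
    "estimate_noise",
    "detect_spikes",
    "firing_rate",
    "lfp_from_wideband",
]

#: MAD -> Gaussian sigma consistency constant.
MAD_TO_SIGMA = 1.0 / 0.6745


@dataclass
class NoiseEstimate:
    """Per-channel robust noise scale (signal units)."""

    per_channel_sigma: np.ndarray
    method: str = "mad"

    def __post_init__(self) -> None:
        self.per_channel_sigma = np.asarray(self.per_channel_sigma, dtype=np.float64)
        if np.any(self.per_channel_sigma < 0):
            raise ValueError("sigma must be >= 0")


@dataclass
class FiringRateSeries:
    """Windowed firing rates: channels x windows, window centers in s."""

    times: np.ndarray
    rates: np.ndarray
    window: float = 2.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=np.float64))
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


def _bandpass_kernel(fs: float, lo: float, hi: float) -> np.ndarray:
    """Symmetric zero-phase FIR band-pass kernel (>= 60 dB stop-band).

    The single-pass Kaiser design is convolved with its reverse, i.e. the
    filter is applied forward and backward in one linear-phase convolution,
    which doubles the stop-band attenuation and leaves phase untouched.
    """
    width = min(lo * 0.5, (fs / 2 - hi)) if hi < fs / 2 else lo * 0.5
    if width <= 0:
        raise ValueError("band does not fit below Nyquist")
    numtaps, beta = signal.kaiserord(ripple=60.0, width=2 * width / fs)
    numtaps |= 1  # odd length -> integer group delay
    cutoffs = [lo, hi] if hi < fs / 2 else lo
    h = signal.firwin(numtaps, cutoffs, window=("kaiser", beta),
                      pass_zero=False, fs=fs)
    return np.convolve(h, h[::-1])


def _zero_phase_filter(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.empty_like(data, dtype=np.float64)
    for c in range(data.shape[0]):
        out[c] = signal.fftconvolve(data[c], kernel, mode="same")
    return out


def preprocess_wideband(
    traces: ContinuousTraces, params: SpikeDetectionParams | None = None
) -> ContinuousTraces:
    """Band-pass 300-12000 Hz (zero phase) then common median reference.

    The per-sample median across channels is subtracted from every channel,
    removing artifacts shared across the probe.  A single-channel recording
    is its own median, so the referenced output is identically zero; this
    is flagged with a warning rather than an error.
    """
    params = params or SpikeDetectionParams()
    if traces.kind != "wideband":
        raise ValueError(f"expected wideband traces, got kind={traces.kind!r}")
    if traces.sample_rate < 2 * params.band_high:
        raise ValueError(
            f"sample rate {traces.sample_rate} Hz is below twice the "
            f"band high-cut {params.band_high} Hz"
        )
    kernel = _bandpass_kernel(traces.sample_rate, params.band_low, params.band_high)
    filtered = _zero_phase_filter(traces.data, kernel)
    if traces.n_channels == 1:
        warnings.warn(
            "common median reference on a single channel zeroes the signal",
            stacklevel=2,
        )
    ref = np.median(filtered, axis=0)
    filtered -= ref[None, :]
    return ContinuousTraces(filtered, traces.sample_rate, list(traces.channel_ids),
                            t0=traces.t0, kind="wideband")


def estimate_noise(traces: ContinuousTraces) -> NoiseEstimate:
    """Per-channel sigma = median(|x - median(x)|) / 0.6745."""
    med = np.median(traces.data, axis=1, keepdims=True)
    mad = np.median(np.abs(traces.data - med), axis=1)
    sigma = mad * MAD_TO_SIGMA
    if np.any(sigma == 0):
        warnings.warn("constant channel(s): noise sigma is 0", stacklevel=2)
    return NoiseEstimate(per_channel_sigma=sigma, method="mad")


def detect_spikes(
    traces: ContinuousTraces,
    noise: NoiseEstimate | None = None,
    params: SpikeDetectionParams | None = None,
) -> SpikeTrainSet:
    """Threshold-crossing peak detection at ``k * sigma``.

    Local extrema beyond the threshold in the configured polarity are
    returned as spike times (sample index / rate + t0); peaks closer than
    the refractory window to a previous peak are suppressed.  Channels with
    zero noise estimate are skipped with a warning.
    """
    params = params or SpikeDetectionParams()
    if params.threshold_k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    if noise is None:
        noise = estimate_noise(traces)
    fs = traces.sample_rate
    distance = max(1, int(round(params.refractory * fs)))
    trains = []
    for c in range(traces.n_channels):
        sigma = noise.per_channel_sigma[c]
        if sigma == 0:
            warnings.warn(
                f"channel {traces.channel_ids[c]!r} has zero noise sigma; skipped",
                stacklevel=2,
            )
            trains.append(np.empty(0))
            continue
        x = traces.data[c]
        height = params.threshold_k * sigma
        if params.polarity == "negative":
            idx, _ = signal.find_peaks(-x, height=height, distance=distance)
        elif params.polarity == "positive":
            idx, _ = signal.find_peaks(x, height=height, distance=distance)
        elif params.polarity == "both":
            idx, _ = signal.find_peaks(np.abs(x), height=height, distance=distance)
        else:
            raise ValueError(f"unknown polarity {params.polarity!r}")
        trains.append(traces.t0 + idx / fs)
    duration = traces.t0 + traces.n_samples / fs
    return SpikeTrainSet(trains, duration=max(duration, np.finfo(float).tiny),
                         channel_ids=list(traces.channel_ids))


def firing_rate(spikes: SpikeTrainSet, window: float = 2.0) -> FiringRateSeries:
    """Spike counts / window in windows tiling [0, duration).

    The last partial window is dropped, so summing ``rates * window`` over
    windows recovers the spike count of the tiled span exactly.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    n_win = int(np.floor(spikes.duration / window))
    edges = np.arange(n_win + 1) * window
    rates = np.zeros((spikes.n_channels, n_win))
    for c, t in enumerate(spikes.trains):
        counts, _ = np.histogram(t, bins=edges)
        rates[c] = counts / window
    centers = edges[:-1] + window / 2
    return FiringRateSeries(times=centers, rates=rates, window=window)


def lfp_from_wideband(
    traces: ContinuousTraces, params: SpikeDetectionParams | None = None
) -> ContinuousTraces:
    """FIR low-pass then decimate the wideband signal to the LFP rate.

    The decimation factor is ``round(fs / lfp_rate)``; the anti-alias
    corner (default 160 Hz) sits below the post-decimation Nyquist.  The
    resulting rate is ``fs / factor`` (400.2 Hz for TDT's 24414.0625 Hz
    wideband and a 400 Hz target).
    """
    params = params or SpikeDetectionParams()
    fs = traces.sample_rate
    factor = int(round(fs / params.lfp_rate))
    if factor < 2:
        raise ValueError("wideband rate must exceed the LFP target rate")
    out_fs = fs / factor
    if params.lfp_corner >= out_fs / 2:
        raise ValueError("anti-alias corner must sit below the decimated Nyquist")
    width = (out_fs / 2 - params.lfp_corner) * 2
    numtaps, beta = signal.kaiserord(ripple=60.0, width=width / fs)
    numtaps |= 1
    h = signal.firwin(numtaps, params.lfp_corner, window=("kaiser", beta), fs=fs)
    kernel = np.convolve(h, h[::-1])
    low = _zero_phase_filter(traces.data, kernel)
    return ContinuousTraces(low[:, ::factor], out_fs, list(traces.channel_ids),
                            t0=traces.t0, kind="lfp")
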