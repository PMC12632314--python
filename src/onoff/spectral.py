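"""Multitaper (DPSS) spectrograms, band power and normalization.

Power spectral density is estimated with a short-time Fourier transform
over 4-s Slepian windows (time-half-bandwidth NW=4, 2K-1 = 7 tapers,
eigenvalue-weighted) and 50% overlap.  Slow-wave activity (SWA) is the
integral of the PSD over the delta band (0.5-4 Hz), conventionally
expressed relative to the NREM mean of a baseline period or to a
contralateral control probe.

PSD units are one-sided power per Hz, so a band integral equals that
band's contribution to signal variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as sig_windows

from .config import SpectralParams
from .intervals import merge_union
from .types import ContinuousTraces, IntervalSet

log = logging.getLogger(__name__)

__all__ = [
    "Spectrogram",
    "BandpowerSeries",
    "spectrogram",
    "bandpower",
    "normalize",
    "window_center_mask",
]


@dataclass
class Spectrogram:
    """Multitaper PSD per window: power has shape (channels, windows, freqs)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    channel_ids: list[str]
    params: SpectralParams

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandpowerSeries:
    """Band-integrated power per window: values has shape (channels, windows)."""

    times: np.ndarray
    values: np.ndarray
    band: str
    lo: float
    hi: float
    channel_ids: list[str]
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.normalization == "none" and np.any(self.values < -1e-12):
            raise ValueError("raw band power must be >= 0")


def spectrogram(
    traces: ContinuousTraces, params: SpectralParams | None = None
) -> Spectrogram:
    """Eigenvalue-weighted multitaper PSD in sliding DPSS windows.

    Each window is detrended (constant removal) before tapering so DC does
    not leak into the delta band.  Hop = window x (1 - overlap).
    """
    params = params or SpectralParams()
    fs = traces.sample_rate
    nperseg = int(round(params.window * fs))
    if nperseg > traces.n_samples:
        raise ValueError(
            f"window of {nperseg} samples exceeds signal length {traces.n_samples}"
        )
    hop = max(1, int(round(nperseg * (1.0 - params.overlap))))
    k = params.n_tapers
    tapers, ratios = sig_windows.dpss(nperseg, params.nw, Kmax=k, return_ratios=True)
    weights = ratios / ratios.sum()

    starts = np.arange(0, traces.n_samples - nperseg + 1, hop)
    times = traces.t0 + (starts + nperseg / 2.0) / fs
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    one_sided = np.full(freqs.size, 2.0)
    one_sided[0] = 1.0
    if nperseg % 2 == 0:
        one_sided[-1] = 1.0

    power = np.empty((traces.n_channels, starts.size, freqs.size))
    for c in range(traces.n_channels):
        segs = np.lib.stride_tricks.sliding_window_view(traces.data[c], nperseg)[::hop]
        segs = segs[: starts.size]
        segs = segs - segs.mean(axis=1, keepdims=True)
        acc = np.zeros((starts.size, freqs.size))
        for taper, w in zip(tapers, weights):
            spec = np.fft.rfft(segs * taper[None, :], axis=1)
            acc += w * (spec.real**2 + spec.imag**2)
        power[c] = acc * one_sided[None, :] / fs
    return Spectrogram(times=times, freqs=freqs, power=power,
                       channel_ids=list(traces.channel_ids), params=params)


def bandpower(spec: Spectrogram, band: str | tuple[float, float]) -> BandpowerSeries:
    """Trapezoidal integral of the PSD over a named or explicit band."""
    if isinstance(band, str):
        try:
            lo, hi = spec.params.bands[band]
        except KeyError:
            raise ValueError(
                f"unknown band {band!r}; configured: {sorted(spec.params.bands)}"
            ) from None
        name = band
    else:
        lo, hi = band
        name = f"{lo:g}-{hi:g}Hz"
    nyq = spec.freqs[-1]
    if not (0 <= lo < hi <= nyq + 1e-9):
        raise ValueError(f"band [{lo}, {hi}] Hz outside spectrum [0, {nyq}] Hz")
    mask = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
    values = np.trapezoid(spec.power[:, :, mask], spec.freqs[mask], axis=2)
    return BandpowerSeries(times=spec.times, values=values, band=name,
                           lo=lo, hi=hi, channel_ids=list(spec.channel_ids))


def window_center_mask(times: np.ndarray, windows: IntervalSet) -> np.ndarray:
    """Boolean mask of window centers falling inside the union of windows."""
    win = merge_union(windows)
    mask = np.zeros(times.size, dtype=bool)
    for s, e, _ in win:
        mask |= (times >= s) & (times < e)
    return mask


def normalize(
    series: BandpowerSeries,
    reference_windows: IntervalSet | None = None,
    mode: str = "baseline_nrem_mean",
    partner: BandpowerSeries | None = None,
) -> BandpowerSeries:
    """Express band power relative to a reference.

    ``baseline_nrem_mean`` divides each channel by its mean over windows
    whose centers fall inside ``reference_windows`` (typically the NREM
    bouts of a 12-h baseline light period).  ``contralateral`` divides per
    window and channel by a channel-matched partner series.
    """
    if mode == "baseline_nrem_mean":
        if reference_windows is None or not len(reference_windows):
            raise ValueError("baseline normalization needs non-empty reference windows")
        mask = window_center_mask(series.times, reference_windows)
        if not mask.any():
            raise ValueError("no window centers fall inside the reference windows")
        ref = series.values[:, mask].mean(axis=1, keepdims=True)
        if np.any(ref == 0):
            raise ValueError("zero reference mean; cannot normalize")
        values = series.values / ref
    elif mode == "contralateral":
        if partner is None:
            raise ValueError("contralateral normalization needs a partner series")
        if partner.values.shape != series.values.shape:
            raise ValueError("partner series shape mismatch")
        if np.any(partner.values == 0):
            raise ValueError("zero partner value; cannot normalize")
        values = series.values / partner.values
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return BandpowerSeries(times=series.times, values=values, band=series.band,
                           lo=series.lo, hi=series.hi,
                           channel_ids=list(series.channel_ids),
                           normalization=mode)
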