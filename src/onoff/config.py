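"""Analysis configuration: every numeric parameter of the pipeline.

Defaults equal the published protocol values (detection thresholds, OFF
duration bounds, quorum, spectral windowing, STTC window).  Configs are
plain dataclasses, loadable from a nested YAML file; unknown keys raise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "SpikeDetectionParams",
    "OffParams",
    "SpectralParams",
    "SavgolParams",
    "SttcParams",
    "ActigraphyParams",
    "AnalysisConfig",
    "load_config",
    "dump_config",
]


@dataclass
class SpikeDetectionParams:
    """MUA preprocessing and threshold detection."""

    band_low: float = 300.0        # Hz, high-pass corner
    band_high: float = 12000.0     # Hz, low-pass corner
    threshold_k: float = 4.0       # multiples of MAD-estimated noise
    polarity: str = "negative"     # {"negative", "positive", "both"}
    refractory: float = 0.001      # s, duplicate-peak suppression
    rate_window: float = 2.0       # s, firing-rate window
    lfp_rate: float = 400.0        # Hz, LFP decimation target
    lfp_corner: float = 160.0      # Hz, anti-alias corner


@dataclass
class OffParams:
    """Single-channel and global ON/OFF segmentation rules."""

    min_off: float = 0.050           # s, minimum single-channel OFF
    min_flank_on: float = 0.030      # s, flanking ON requirement
    max_isi_in_on: float = 0.050     # s, ISI >= this breaks an ON run
    quorum: int = 12                 # channels simultaneously OFF
    n_channels: int = 16
    global_off_bounds: tuple[float, float] = (0.050, 0.400)   # s
    global_on_bounds: tuple[float, float] = (0.050, 2.000)    # s
    mode: str = "standard"           # {"standard", "fallback"}
    both_flanks: bool = False        # stricter two-sided flanking rule

    def __post_init__(self) -> None:
        if self.min_off <= 0:
            raise ValueError("min_off must be > 0")
        if not (0 < self.quorum <= self.n_channels):
            raise ValueError("quorum must be in (0, n_channels]")
        for lo, hi in (self.global_off_bounds, self.global_on_bounds):
            if not (0 < lo < hi):
                raise ValueError("duration bounds must satisfy 0 < lo < hi")
        if self.mode not in ("standard", "fallback"):
            raise ValueError("mode must be 'standard' or 'fallback'")


#: Named frequency bands (Hz) used throughout the spectral module.
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (11.0, 16.0),
    "beta": (13.0, 30.0),
}


@dataclass
class SpectralParams:
    """Multitaper short-time spectral estimation."""

    window: float = 4.0          # s, DPSS window length
    nw: float = 4.0              # time-half-bandwidth product
    overlap: float = 0.5         # fraction of window overlap
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.window <= 0 or self.nw <= 0:
            raise ValueError("window and nw must be > 0")
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} edges must be ordered")

    @property
    def n_tapers(self) -> int:
        return int(2 * self.nw - 1)


@dataclass
class SavgolParams:
    """Savitzky-Golay smoothing used before waveform derivatives."""

    window: int = 11      # samples (odd)
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window <= self.polyorder:
            raise ValueError("window must be odd and exceed polyorder")


@dataclass
class SttcParams:
    """Spike-time tiling coefficient parameters."""

    dt: float = 0.005            # s, coincidence half-window (±5 ms)
    clip_epsilon: float = 1e-6   # Fisher-Z clipping
    formula: str = "as_printed"  # {"as_printed", "cutts_eglen"}
    min_epoch: float | None = None  # s; default 2*dt

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 < self.clip_epsilon < 1):
            raise ValueError("clip_epsilon must be in (0, 1)")
        if self.formula not in ("as_printed", "cutts_eglen"):
            raise ValueError("formula must be 'as_printed' or 'cutts_eglen'")
        if self.min_epoch is None:
            self.min_epoch = 2 * self.dt


@dataclass
class ActigraphyParams:
    """Video-pose actigraphy sleep classification."""

    frame_rate: float = 1.0            # Hz
    threshold_stats: str = "raw"       # {"raw", "zscored"}: series whose
    #                                     mean/std define the cut -mean/std
    mad_constant: float = 1.4826       # Gaussian consistency constant

    def __post_init__(self) -> None:
        if self.threshold_stats not in ("raw", "zscored"):
            raise ValueError("threshold_stats must be 'raw' or 'zscored'")


@dataclass
class AnalysisConfig:
    """Top-level configuration grouping every stage's parameters."""

    spike_detection: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    off: OffParams = field(default_factory=OffParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    savgol: SavgolParams = field(default_factory=SavgolParams)
    sttc: SttcParams = field(default_factory=SttcParams)
    actigraphy: ActigraphyParams = field(default_factory=ActigraphyParams)
    include_unscored: bool = False   # include Unsure/Artifact bouts in conditions

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "spike_detection": SpikeDetectionParams,
    "off": OffParams,
    "spectral": SpectralParams,
    "savgol": SavgolParams,
    "sttc": SttcParams,
    "actigraphy": ActigraphyParams,
}


def _build(cls, payload: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is OffParams:
        for key in ("global_off_bounds", "global_on_bounds"):
            if key in payload:
                payload[key] = tuple(payload[key])
    return cls(**payload)


def load_config(path) -> AnalysisConfig:
    """Load a nested YAML config; absent sections keep their defaults."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, value in payload.items():
        if name in _SECTION_TYPES:
            kwargs[name] = _build(_SECTION_TYPES[name], dict(value or {}))
        elif name == "include_unscored":
            kwargs[name] = bool(value)
        else:
            raise ValueError(f"unknown config section {name!r}")
    return AnalysisConfig(**kwargs)


def dump_config(config: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
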