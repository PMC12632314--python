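"""Domain containers shared by every analysis stage.

All times are seconds from session start and every interval is half-open
``[start, end)``.  The containers are deliberately thin: plain dataclasses
wrapping numpy arrays, validated on construction, with TSV / flat-binary
persistence handled in :mod:`onoff.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "VIGILANCE_STATES",
    "SLEEP_STATES",
    "ContinuousTraces",
    "SpikeTrainSet",
    "IntervalSet",
    "Hypnogram",
    "StimulationStage",
    "StimulationProtocol",
    "PoseTrack",
]

#: Fixed vocabulary of vigilance states produced by sleep scoring.
VIGILANCE_STATES = ("Wake", "NREM", "REM", "IS", "Unsure", "Artifact")

#: States counted as sleep when comparing against actigraphy predictions.
SLEEP_STATES = ("NREM", "REM", "IS")

TRACE_KINDS = ("wideband", "lfp", "eeg", "emg")


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ContinuousTraces:
    """Multichannel regularly-sampled signal (wideband, LFP, EEG or EMG).

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` array of signal values.
    sample_rate:
        Sampling rate in Hz.
    channel_ids:
        Ordered, unique channel labels.
    t0:
        Time of the first sample, seconds from session start.
    kind:
        One of ``{"wideband", "lfp", "eeg", "emg"}``.
    """

    data: np.ndarray
    sample_rate: float
    channel_ids: list[str]
    t0: float = 0.0
    kind: str = "lfp"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        self.channel_ids = [str(c) for c in self.channel_ids]
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match number of channels")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, channel_id: str) -> int:
        return self.channel_ids.index(str(channel_id))


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike times over a known recording span."""

    trains: list[np.ndarray]
    duration: float
    channel_ids: list[str]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.trains) != len(self.channel_ids):
            raise ValueError("number of trains must match channel_ids")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        clean = []
        for cid, t in zip(self.channel_ids, self.trains):
            t = np.asarray(t, dtype=np.float64).ravel()
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"spike train {cid!r} must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError(f"spike times of {cid!r} must lie in [0, duration)")
            clean.append(t)
        self.trains = clean

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    def merged(self) -> np.ndarray:
        """All spike times pooled across channels, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    def total_count(self) -> int:
        return int(sum(t.size for t in self.trains))


@dataclass
class IntervalSet:
    """Labelled, sorted, half-open time intervals.

    Intervals sharing a label must be non-overlapping and sorted by start.
    Zero-width intervals (``start == end``) are tolerated so that degenerate
    single-spike ON runs can be represented; they have zero measure.
    """

    starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.float64).ravel()
        self.ends = np.asarray(self.ends, dtype=np.float64).ravel()
        self.labels = [str(l) for l in self.labels]
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise ValueError("starts, ends and labels must have equal length")
        if np.any(self.ends < self.starts):
            raise ValueError("every interval must satisfy start <= end")
        # sort by (label, start) and check per-label disjointness
        if len(self) > 1:
            order = np.lexsort((self.starts, np.array(self.labels, dtype=object)))
            self.starts = self.starts[order]
            self.ends = self.ends[order]
            self.labels = [self.labels[i] for i in order]
            for i in range(1, len(self)):
                if self.labels[i] == self.labels[i - 1] and self.starts[i] < self.ends[i - 1]:
                    raise ValueError(
                        f"overlapping intervals with label {self.labels[i]!r} "
                        f"at {self.starts[i]:.6f}s"
                    )

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[float, float, str]]) -> "IntervalSet":
        tuples = list(tuples)
        if not tuples:
            return cls()
        s, e, l = zip(*tuples)
        return cls(np.array(s), np.array(e), list(l))

    @classmethod
    def from_arrays(cls, starts, ends, label: str = "") -> "IntervalSet":
        starts = np.asarray(starts, dtype=np.float64).ravel()
        return cls(starts, np.asarray(ends, dtype=np.float64).ravel(), [label] * starts.size)

    def __len__(self) -> int:
        return self.starts.size

    def __iter__(self):
        for s, e, l in zip(self.starts, self.ends, self.labels):
            yield float(s), float(e), l

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and self.labels == other.labels
        )

    # -- queries -------------------------------------------------------------
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def total_duration(self) -> float:
        """Total measure; per-label intervals are disjoint so this is a sum."""
        return float(np.sum(self.ends - self.starts))

    def select(self, label: str) -> "IntervalSet":
        mask = [l == label for l in self.labels]
        idx = np.flatnonzero(mask)
        return IntervalSet(self.starts[idx], self.ends[idx], [self.labels[i] for i in idx])

    def label_set(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)


@dataclass
class Hypnogram:
    """Vigilance-state segmentation: sorted, non-overlapping state bouts."""

    states: list[str]
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.states = [str(s) for s in self.states]
        self.starts = np.asarray(self.starts, dtype=np.float64).ravel()
        self.ends = np.asarray(self.ends, dtype=np.float64).ravel()
        if not (len(self.states) == self.starts.size == self.ends.size):
            raise ValueError("states, starts and ends must have equal length")
        for s in self.states:
            if s not in VIGILANCE_STATES:
                raise ValueError(f"unknown vigilance state {s!r}")
        if np.any(self.ends <= self.starts):
            raise ValueError("every bout must satisfy start < end")
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.states = [self.states[i] for i in order]
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("bouts must be non-overlapping")

    def __len__(self) -> int:
        return len(self.states)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.states == other.states
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def bouts_of(self, *states: str, exclude_unscored: bool = False) -> IntervalSet:
        """Bouts of the requested states as an :class:`IntervalSet`.

        With ``exclude_unscored`` the Unsure/Artifact bouts are carved out of
        the returned windows (they never are among the requested states in
        normal use, so this only matters for aggregate windows).
        """
        idx = [i for i, s in enumerate(self.states) if s in states]
        out = IntervalSet(
            self.starts[idx], self.ends[idx], [self.states[i] for i in idx]
        )
        return out

    def state_at(self, t: float) -> str | None:
        i = np.searchsorted(self.starts, t, side="right") - 1
        if i >= 0 and t < self.ends[i]:
            return self.states[i]
        return None

    def span(self) -> tuple[float, float]:
        if not len(self):
            raise ValueError("empty hypnogram has no span")
        return float(self.starts[0]), float(self.ends[-1])

    def shifted(self, dt: float) -> "Hypnogram":
        return Hypnogram(list(self.states), self.starts + dt, self.ends + dt)


@dataclass
class StimulationStage:
    """One stage of a pulsed laser protocol."""

    pulse_rate: float  # Hz
    on_time: float  # ms of light per pulse
    stage_duration: float  # s of pulsing
    break_duration: float  # s of darkness after the stage
    repeat_until_sleep: bool = False

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0 or self.on_time <= 0 or self.stage_duration <= 0:
            raise ValueError("pulse_rate, on_time and stage_duration must be > 0")
        if self.break_duration < 0:
            raise ValueError("break_duration must be >= 0")
        if self.pulse_rate * self.on_time > 1000.0:
            raise ValueError("duty cycle exceeds 1 (pulse_rate * on_time > 1000 ms)")


@dataclass
class StimulationProtocol:
    """Ordered sequence of pulse-train stages."""

    stages: list[StimulationStage]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")


@dataclass
class PoseTrack:
    """Pose-tracking trajectories: frames x nodes x (x, y) in pixels."""

    positions: np.ndarray
    frame_rate: float
    node_names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, nodes, 2)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        self.node_names = [str(n) for n in self.node_names]
        if len(self.node_names) != self.positions.shape[1]:
            raise ValueError("node_names length must match node dimension")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain missing values; fill gaps first")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[1]

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)
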