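"""Readers and writers for the package's on-disk contract.

Tables (hypnograms, spike times, intervals, pose) are TSV with a one-line
header.  Continuous traces are a flat channel-major binary file with a JSON
sidecar carrying ``{channel_ids, sample_rate, dtype, t0, kind, n_samples}``.
Spectrograms go to HDF5.  Every writer/reader pair round-trips valid
objects exactly (bit-exact for labels and integers, to representation
precision for floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ContinuousTraces,
    Hypnogram,
    IntervalSet,
    PoseTrack,
    SpikeTrainSet,
    StimulationProtocol,
    StimulationStage,
)

__all__ = [
    "write_traces", "read_traces",
    "write_hypnogram", "read_hypnogram",
    "write_spikes", "read_spikes",
    "write_intervals", "read_intervals",
    "write_pose", "read_pose",
    "write_protocol", "read_protocol",
    "write_spectrogram", "read_spectrogram",
    "save", "load",
]

_FLOAT_FMT = "%.17g"  # shortest round-trip representation for float64


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    return df


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return df[col].astype(np.float64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: column {col!r} is not numeric ({exc})") from exc


# ---------------------------------------------------------------- traces ---

def write_traces(traces: ContinuousTraces, path) -> None:
    """Write channel-major binary ``<path>.bin`` plus JSON sidecar ``<path>.json``."""
    path = Path(path)
    data = np.ascontiguousarray(traces.data)
    data.tofile(path.with_suffix(".bin"))
    meta = {
        "channel_ids": traces.channel_ids,
        "sample_rate": traces.sample_rate,
        "dtype": str(data.dtype),
        "t0": traces.t0,
        "kind": traces.kind,
        "n_samples": traces.n_samples,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_traces(path) -> ContinuousTraces:
    path = Path(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: bad JSON sidecar ({exc})") from exc
    for key in ("channel_ids", "sample_rate", "dtype", "t0", "kind", "n_samples"):
        if key not in meta:
            raise ParseError(f"{path}: sidecar missing field {key!r}")
    data = np.fromfile(path.with_suffix(".bin"), dtype=np.dtype(meta["dtype"]))
    n_ch = len(meta["channel_ids"])
    if n_ch and data.size % n_ch:
        raise ParseError(f"{path}: binary size {data.size} not divisible by {n_ch} channels")
    data = data.reshape(n_ch, -1)
    if data.shape[1] != meta["n_samples"]:
        raise ParseError(
            f"{path}: expected {meta['n_samples']} samples/channel, found {data.shape[1]}"
        )
    return ContinuousTraces(
        data, float(meta["sample_rate"]), list(meta["channel_ids"]),
        t0=float(meta["t0"]), kind=meta["kind"],
    )


# ------------------------------------------------------------- hypnogram ---

def write_hypnogram(hyp: Hypnogram, path) -> None:
    df = pd.DataFrame({"state": hyp.states, "start_s": hyp.starts, "end_s": hyp.ends})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_hypnogram(path) -> Hypnogram:
    df = _read_tsv(path, ["state", "start_s", "end_s"])
    try:
        return Hypnogram(
            list(df["state"]), _to_float(df, "start_s", path), _to_float(df, "end_s", path)
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- spikes ---

def write_spikes(spikes: SpikeTrainSet, path) -> None:
    """Columnar TSV ``channel, time_s``; recording duration and channel order
    travel in a companion ``<path>.meta.json``."""
    path = Path(path)
    chan = np.concatenate(
        [np.full(t.size, cid, dtype=object) for cid, t in zip(spikes.channel_ids, spikes.trains)]
        or [np.empty(0, dtype=object)]
    )
    times = np.concatenate(spikes.trains or [np.empty(0)])
    pd.DataFrame({"channel": chan, "time_s": times}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    meta = {"duration": spikes.duration, "channel_ids": spikes.channel_ids}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_spikes(path, duration: float | None = None,
                channel_ids: list[str] | None = None) -> SpikeTrainSet:
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        duration = duration if duration is not None else meta["duration"]
        channel_ids = channel_ids if channel_ids is not None else meta["channel_ids"]
    df = _read_tsv(path, ["channel", "time_s"])
    times = _to_float(df, "time_s", path)
    chans = df["channel"].to_numpy()
    if channel_ids is None:
        channel_ids = sorted(set(chans))
    if duration is None:
        duration = float(times.max()) + 1.0 if times.size else 1.0
    trains = [np.sort(times[chans == cid]) for cid in channel_ids]
    try:
        return SpikeTrainSet(trains, duration=float(duration), channel_ids=list(channel_ids))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ------------------------------------------------------------- intervals ---

def write_intervals(iv: IntervalSet, path) -> None:
    df = pd.DataFrame({"label": iv.labels, "start_s": iv.starts, "end_s": iv.ends})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_intervals(path) -> IntervalSet:
    df = _read_tsv(path, ["label", "start_s", "end_s"])
    try:
        return IntervalSet(
            _to_float(df, "start_s", path), _to_float(df, "end_s", path), list(df["label"])
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------ pose ---

def write_pose(track: PoseTrack, path) -> None:
    n_f, n_n = track.n_frames, track.n_nodes
    frames = np.repeat(np.arange(n_f), n_n)
    nodes = np.tile(np.array(track.node_names, dtype=object), n_f)
    xy = track.positions.reshape(-1, 2)
    df = pd.DataFrame({"frame": frames, "node": nodes, "x": xy[:, 0], "y": xy[:, 1]})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    Path(str(path) + ".meta.json").write_text(
        json.dumps({"frame_rate": track.frame_rate, "node_names": track.node_names})
    )


def read_pose(path, frame_rate: float | None = None) -> PoseTrack:
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    node_names = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        frame_rate = frame_rate if frame_rate is not None else meta["frame_rate"]
        node_names = meta.get("node_names")
    if frame_rate is None:
        frame_rate = 1.0
    df = _read_tsv(path, ["frame", "node", "x", "y"])
    frames = _to_float(df, "frame", path).astype(np.int64)
    x = _to_float(df, "x", path)
    y = _to_float(df, "y", path)
    nodes = df["node"].to_numpy()
    if node_names is None:
        node_names = list(dict.fromkeys(nodes))
    n_f = int(frames.max()) + 1 if frames.size else 0
    pos = np.full((n_f, len(node_names), 2), np.nan)
    node_idx = {n: i for i, n in enumerate(node_names)}
    pos[frames, [node_idx[n] for n in nodes], :] = np.column_stack([x, y])
    if np.any(~np.isfinite(pos)):
        raise ParseError(f"{path}: missing frame/node combinations")
    return PoseTrack(pos, frame_rate=float(frame_rate), node_names=list(node_names))


# -------------------------------------------------------------- protocol ---

def write_protocol(protocol: StimulationProtocol, path) -> None:
    stages = [
        {
            "pulse_rate": st.pulse_rate,
            "on_time": st.on_time,
            "stage_duration": st.stage_duration,
            "break_duration": st.break_duration,
            "repeat_until_sleep": st.repeat_until_sleep,
        }
        for st in protocol.stages
    ]
    Path(path).write_text(json.dumps({"stages": stages}, indent=1))


def read_protocol(path) -> StimulationProtocol:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: bad JSON ({exc})") from exc
    try:
        stages = [StimulationStage(**st) for st in obj["stages"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: invalid protocol ({exc})") from exc
    return StimulationProtocol(stages)


# ----------------------------------------------------------- spectrogram ---

def write_spectrogram(path, times: np.ndarray, freqs: np.ndarray, power: np.ndarray,
                      channel_ids: list[str]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=times)
        f.create_dataset("freqs", data=freqs)
        f.create_dataset("power", data=power)
        f.create_dataset("channel_ids", data=np.array(channel_ids, dtype="S"))


def read_spectrogram(path):
    import h5py

    with h5py.File(path, "r") as f:
        times = f["times"][:]
        freqs = f["freqs"][:]
        power = f["power"][:]
        channel_ids = [c.decode() for c in f["channel_ids"][:]]
    return times, freqs, power, channel_ids


# ------------------------------------------------------------- dispatch ----

_WRITERS = {
    ContinuousTraces: write_traces,
    Hypnogram: write_hypnogram,
    SpikeTrainSet: write_spikes,
    IntervalSet: write_intervals,
    PoseTrack: write_pose,
    StimulationProtocol: write_protocol,
}

_READERS = {
    ContinuousTraces: read_traces,
    Hypnogram: read_hypnogram,
    SpikeTrainSet: read_spikes,
    IntervalSet: read_intervals,
    PoseTrack: read_pose,
    StimulationProtocol: read_protocol,
}


def save(obj, path) -> None:
    """Write any domain object using its canonical format."""
    for cls, fn in _WRITERS.items():
        if isinstance(obj, cls):
            fn(obj, path)
            return
    raise TypeError(f"no writer for {type(obj).__name__}")


def load(cls, path):
    """Read a domain object of class ``cls`` from ``path``."""
    try:
        return _READERS[cls](path)
    except KeyError:
        raise TypeError(f"no reader for {cls.__name__}") from None
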