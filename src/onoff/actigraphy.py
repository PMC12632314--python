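"""Video-pose actigraphy: movement scoring, sleep labelling, validation.

From an overhead pose track, the per-frame movement is the squared
displacement (dX^2 + dY^2) of each tracked node, averaged across nodes.
The movement series is robust Z-scored (median / 1.4826 MAD) and a single
threshold tau = -mean/std splits sleep (below) from wake (above).  The
mean and std defining tau are taken from the raw movement series by
default; computed on the z-scored series itself they place the cut inside
the active-movement distribution (``threshold_stats`` selects the
variant).  The module also scores the floor-texture-recognition novelty
ratio: the fraction of test-phase time spent on the novel side of the
arena.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import ActigraphyParams
from .intervals import intersect, merge_union
from .types import Hypnogram, IntervalSet, PoseTrack, SLEEP_STATES

log = logging.getLogger(__name__)

__all__ = [
    "MovementSeries",
    "ActigraphyResult",
    "movement_series",
    "classify_sleep",
    "predicted_sleep_intervals",
    "sleep_fraction_error",
    "novelty_ratio",
]


@dataclass
class MovementSeries:
    """Node-averaged squared displacement per frame transition (pixels^2)."""

    movement: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.movement = np.asarray(self.movement, dtype=np.float64)
        if np.any(self.movement < 0):
            raise ValueError("movement must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass
class ActigraphyResult:
    """Per-frame sleep/wake labels with the threshold that produced them."""

    labels: np.ndarray            # bool, True = sleep, one per transition
    threshold: float              # z-units
    sleep_fraction: float
    zscores: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.sleep_fraction <= 1.0):
            raise ValueError("sleep_fraction must be in [0, 1]")


def movement_series(track: PoseTrack) -> MovementSeries:
    """Per-node (dX^2 + dY^2) across frame changes, averaged over nodes."""
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames to compute movement")
    d = np.diff(track.positions, axis=0)          # (frames-1, nodes, 2)
    per_node = (d**2).sum(axis=2)
    return MovementSeries(per_node.mean(axis=1), frame_rate=track.frame_rate)


def classify_sleep(
    movement: MovementSeries, params: ActigraphyParams | None = None
) -> ActigraphyResult:
    """Threshold the robust-z movement at tau = -mean/std.

    Degenerate series: if the MAD is zero the z-scoring falls back to
    standard-deviation scaling; if that is also zero (no movement
    variation at all) every frame is labelled wake, since there is no
    evidence of a quiescence/activity bimodality.
    """
    params = params or ActigraphyParams()
    m = movement.movement
    med = np.median(m)
    mad = np.median(np.abs(m - med))
    scale = params.mad_constant * mad
    if scale == 0:
        warnings.warn("zero MAD; falling back to standard-deviation scaling",
                      stacklevel=2)
        scale = m.std()
        if scale == 0:
            warnings.warn("degenerate movement series; labelling all frames wake",
                          stacklevel=2)
            z = np.zeros_like(m)
            return ActigraphyResult(labels=np.zeros(m.size, dtype=bool),
                                    threshold=float("-inf"),
                                    sleep_fraction=0.0, zscores=z)
    z = (m - med) / scale
    if params.threshold_stats == "raw":
        tau = -m.mean() / m.std() if m.std() > 0 else 0.0
    else:
        tau = -z.mean() / z.std() if z.std() > 0 else 0.0
    labels = z < tau
    return ActigraphyResult(labels=labels, threshold=float(tau),
                            sleep_fraction=float(labels.mean()), zscores=z)


def predicted_sleep_intervals(
    result: ActigraphyResult, movement: MovementSeries, t0: float = 0.0
) -> IntervalSet:
    """Contiguous sleep-labelled frame transitions as an IntervalSet.

    Transition i covers [t0 + i/rate, t0 + (i+1)/rate)."""
    dt = 1.0 / movement.frame_rate
    idx = np.flatnonzero(result.labels)
    if not idx.size:
        return IntervalSet()
    return merge_union(
        IntervalSet.from_arrays(t0 + idx * dt, t0 + (idx + 1) * dt, "sleep"),
        label="sleep",
    )


def sleep_fraction_error(
    pred: ActigraphyResult,
    movement: MovementSeries,
    reference: Hypnogram,
    window: IntervalSet,
    t0: float = 0.0,
) -> float:
    """Signed error: predicted sleep fraction minus reference sleep fraction.

    Reference sleep is NREM + REM + IS time; Unsure is excluded from sleep
    but (like everything else) counts toward the window duration.  Both
    fractions are computed over the same window.
    """
    total = merge_union(window).total_duration()
    if total <= 0:
        raise ValueError("window must have positive duration")
    pred_iv = predicted_sleep_intervals(pred, movement, t0=t0)
    pred_frac = intersect(pred_iv, window).total_duration() / total
    ref_iv = reference.bouts_of(*SLEEP_STATES)
    ref_frac = intersect(ref_iv, window).total_duration() / total
    return float(pred_frac - ref_frac)


def novelty_ratio(
    track: PoseTrack,
    arena_split: float,
    novel_side: str = "right",
    window_s: float = 300.0,
    node: str = "nose",
    arena_bounds: tuple[float, float] | None = None,
) -> float:
    """Fraction of test-phase frames with the nose on the novel side.

    ``arena_split`` is the x boundary between floor textures; the window is
    the first ``window_s`` seconds (the 5-minute testing phase).  Positions
    outside ``arena_bounds`` are clamped with a warning.
    """
    if novel_side not in ("left", "right"):
        raise ValueError("novel_side must be 'left' or 'right'")
    n = min(track.n_frames, int(round(window_s * track.frame_rate)))
    if n < 1:
        raise ValueError("window contains no frames")
    x = track.positions[:n, track.node_index(node), 0].copy()
    if arena_bounds is not None:
        lo, hi = arena_bounds
        out = (x < lo) | (x > hi)
        if out.any():
            warnings.warn(f"{int(out.sum())} frames outside arena bounds; clamped",
                          stacklevel=2)
            x = np.clip(x, lo, hi)
    on_right = x >= arena_split
    frac_right = float(on_right.mean())
    return frac_right if novel_side == "right" else 1.0 - frac_right
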