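"""Spike-time tiling coefficient (STTC) synchrony matrices.

The STTC is a firing-rate-robust pairwise synchrony measure.  For trains A
and B on a common recording window: T_A is the proportion of A's spikes
with at least one B spike within +/-dt (5 ms default); P_A is the fraction
of the recording time already tiled by +/-dt windows around A's own spikes
(the chance level implied by A's rate).  Two formula variants are
provided:

``as_printed``    0.5 * [ (T_A - P_A)/(1 - T_A*P_A) + (T_B - P_B)/(1 - T_B*P_B) ]
``cutts_eglen``   0.5 * [ (T_A - P_B)/(1 - T_A*P_B) + (T_B - P_A)/(1 - T_B*P_A) ]

The first pairs each train's coincidence proportion with its own tiling
fraction; the second is the original cross-paired form.  Values are
clipped to [-1+eps, 1-eps] before the Fisher-Z transform z = atanh(r).
Coefficients are computed per epoch (continuous bout of a condition) and
averaged across epochs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import SttcParams
from .intervals import merge_union
from .types import IntervalSet, SpikeTrainSet

log = logging.getLogger(__name__)

__all__ = [
    "SttcMatrix",
    "sttc_pair",
    "sttc_condition",
    "fisher_z",
    "condition_difference",
]


@dataclass
class SttcMatrix:
    """Symmetric channel-pair STTC matrix with a Fisher-Z view."""

    values: np.ndarray
    channel_ids: list[str]
    n_epochs: int
    condition: str = ""
    clip_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.channel_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square, matching channel_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("values must be symmetric")

    @property
    def z_values(self) -> np.ndarray:
        return fisher_z(self.values, self.clip_epsilon)

    def offdiag_mean(self) -> float:
        """Mean coefficient over unique off-diagonal pairs (NaNs ignored)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return float(np.nanmean(self.values[iu]))


def _merged_tiles(train: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint union runs of [t-dt, t+dt] around sorted spike times."""
    if not train.size:
        return np.empty(0), np.empty(0)
    gap = np.flatnonzero(np.diff(train) > 2 * dt)
    starts = train[np.concatenate([[0], gap + 1])] - dt
    ends = train[np.concatenate([gap, [train.size - 1]])] + dt
    return starts, ends


def _tiled_fraction(train: np.ndarray, dt: float, windows: IntervalSet) -> float:
    """Measure of the union of [t-dt, t+dt] around spikes, clipped to the
    windows, as a fraction of the total window duration."""
    total = windows.total_duration()
    ts, te = _merged_tiles(np.asarray(train, dtype=np.float64), dt)
    if not ts.size:
        return 0.0
    covered = 0.0
    for s, e, _ in merge_union(windows):
        covered += float(np.sum(np.maximum(
            0.0, np.minimum(te, e) - np.maximum(ts, s)
        )))
    return covered / total


def _coincident_fraction(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in ``a`` with at least one ``b`` spike within +/-dt."""
    lo = np.searchsorted(b, a - dt, side="left")
    hi = np.searchsorted(b, a + dt, side="right")
    return float(np.mean(hi > lo))


def sttc_pair(
    train_a: np.ndarray,
    train_b: np.ndarray,
    window: IntervalSet | float,
    params: SttcParams | None = None,
) -> float:
    """STTC of two trains on a window (scalar duration means [0, T)).

    Returns NaN (missing) when either restricted train is empty or a
    denominator degenerates; missingness is distinct from zero synchrony.
    """
    params = params or SttcParams()
    if isinstance(window, (int, float)):
        windows = IntervalSet.from_arrays([0.0], [float(window)], "window")
    else:
        windows = merge_union(window)
    if not len(windows) or windows.total_duration() <= 0:
        raise ValueError("window must have positive duration")

    a = np.asarray(train_a, dtype=np.float64)
    b = np.asarray(train_b, dtype=np.float64)
    # restrict to the window union
    def _inside(t: np.ndarray) -> np.ndarray:
        keep = np.zeros(t.size, dtype=bool)
        lo = np.searchsorted(t, windows.starts, side="left")
        hi = np.searchsorted(t, windows.ends, side="left")
        for i0, i1 in zip(lo, hi):
            keep[i0:i1] = True
        return t[keep]

    a, b = _inside(np.sort(a)), _inside(np.sort(b))
    if a.size == 0 or b.size == 0:
        return float("nan")

    dt = params.dt
    t_a = _coincident_fraction(a, b, dt)
    t_b = _coincident_fraction(b, a, dt)
    p_a = _tiled_fraction(a, dt, windows)
    p_b = _tiled_fraction(b, dt, windows)

    if params.formula == "as_printed":
        pairs = ((t_a, p_a), (t_b, p_b))
    else:
        pairs = ((t_a, p_b), (t_b, p_a))
    terms = []
    for t_x, p_x in pairs:
        denom = 1.0 - t_x * p_x
        if abs(denom) < 1e-12:
            warnings.warn("degenerate STTC denominator; returning missing", stacklevel=2)
            return float("nan")
        terms.append((t_x - p_x) / denom)
    return float(0.5 * sum(terms))


def sttc_condition(
    spikes: SpikeTrainSet,
    condition_bouts: IntervalSet,
    params: SttcParams | None = None,
    condition: str = "",
) -> SttcMatrix:
    """Per-epoch STTC for every unordered channel pair, averaged over epochs.

    Each continuous bout of the condition is one epoch; bouts shorter than
    ``min_epoch`` (default 2 dt, below which the tiling fraction is
    ill-defined) are skipped with a log entry.  Pairs with no valid epoch
    get a missing (NaN) entry.  The diagonal is 1 where the channel has
    any spike in the condition.
    """
    params = params or SttcParams()
    bouts = merge_union(condition_bouts)
    if not len(bouts):
        raise ValueError("condition must contain at least one bout")
    n = spikes.n_channels
    dt = params.dt
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    n_used = 0
    any_spike = np.zeros(n, dtype=bool)
    for s, e, _ in bouts:
        if e - s < params.min_epoch:
            log.info("skipping %.3f s epoch shorter than %.3f s", e - s, params.min_epoch)
            continue
        n_used += 1
        win = IntervalSet.from_arrays([s], [e], "epoch")
        trains = []
        p = np.empty(n)
        for c, t in enumerate(spikes.trains):
            tc = t[(t >= s) & (t < e)]
            trains.append(tc)
            any_spike[c] |= tc.size > 0
            p[c] = _tiled_fraction(tc, dt, win) if tc.size else np.nan
        for i in range(n):
            if not trains[i].size:
                continue
            for j in range(i + 1, n):
                if not trains[j].size:
                    continue
                t_i = _coincident_fraction(trains[i], trains[j], dt)
                t_j = _coincident_fraction(trains[j], trains[i], dt)
                if params.formula == "as_printed":
                    pairs = ((t_i, p[i]), (t_j, p[j]))
                else:
                    pairs = ((t_i, p[j]), (t_j, p[i]))
                denoms = [1.0 - tx * px for tx, px in pairs]
                if any(abs(d) < 1e-12 for d in denoms):
                    continue
                r = 0.5 * sum((tx - px) / d for (tx, px), d in zip(pairs, denoms))
                acc[i, j] += r
                cnt[i, j] += 1
    if n_used == 0:
        raise ValueError("no epoch reaches the minimum usable length")
    values = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    ok = cnt[iu, ju] > 0
    values[iu[ok], ju[ok]] = acc[iu[ok], ju[ok]] / cnt[iu[ok], ju[ok]]
    values[ju[ok], iu[ok]] = values[iu[ok], ju[ok]]
    np.fill_diagonal(values, np.where(any_spike, 1.0, np.nan))
    return SttcMatrix(values=values, channel_ids=list(spikes.channel_ids),
                      n_epochs=n_used, condition=condition,
                      clip_epsilon=params.clip_epsilon)


def fisher_z(r, clip_epsilon: float = 1e-6):
    """z = atanh(r) after clipping r to [-1+eps, 1-eps]."""
    r = np.asarray(r, dtype=np.float64)
    out = np.arctanh(np.clip(r, -1.0 + clip_epsilon, 1.0 - clip_epsilon))
    return float(out) if out.ndim == 0 else out


def condition_difference(
    mat_a: SttcMatrix, mat_b: SttcMatrix, space: str = "z"
) -> np.ndarray:
    """Entry-wise condition difference, in Fisher-Z space by default.

    Z-space differences are the statistically stable convention; raw
    coefficient differences (``space="r"``) match what synchrony matrices
    display.
    """
    if mat_a.channel_ids != mat_b.channel_ids:
        raise ValueError("matrices are not channel-aligned")
    if space == "z":
        return mat_a.z_values - mat_b.z_values
    if space == "r":
        return mat_a.values - mat_b.values
    raise ValueError("space must be 'z' or 'r'")
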