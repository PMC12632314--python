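"""Condition-window extraction from a hypnogram.

Conditions are defined relative to two anchors: light onset on the
experiment day and the end of the sleep-deprivation period (SD; 5 h of
enforced wakefulness from light onset).  ``baseline_12h`` is all NREM in
the baseline light period (24 h before the experiment's light onset);
``recovery_1h_nrem`` is the first hour of *cumulative* NREM after SD end,
truncating the final bout so the total is exactly 3600 s;
``circadian_matched_1h`` is the same accumulation starting exactly 24 h
before the recovery start.  Unsure and Artifact bouts are excluded from
every condition by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import intersect, merge_union
from .types import Hypnogram, IntervalSet

log = logging.getLogger(__name__)

__all__ = ["ConditionSpec", "ResolvedCondition", "accumulate_state_time", "resolve_condition"]

CONDITION_NAMES = (
    "baseline_12h",
    "sd_first_hour",
    "induction",
    "recovery_1h_nrem",
    "recovery_first_30min",
    "circadian_matched_1h",
)

DAY = 86400.0
SD_LENGTH = 5 * 3600.0
INDUCTION_LENGTH = 1800.0


@dataclass
class ConditionSpec:
    """A named condition plus the session anchors that locate it.

    ``light_onset`` is light onset on the experiment day (s from session
    start); ``sd_end`` the end of sleep deprivation.  The baseline light
    period is the 12 h starting one day before ``light_onset``.
    """

    name: str
    light_onset: float
    sd_end: float | None = None

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {self.name!r}; one of {CONDITION_NAMES}")
        needs_sd = self.name not in ("baseline_12h", "sd_first_hour")
        if needs_sd and self.sd_end is None:
            raise ValueError(f"condition {self.name!r} needs the sd_end anchor")


@dataclass
class ResolvedCondition:
    """Windows of one condition, with the accumulation bookkeeping."""

    windows: IntervalSet
    requested_s: float | None = None   # cumulative quota, if any
    achieved_s: float = 0.0
    short: bool = False                # quota not reached

    def __post_init__(self) -> None:
        self.achieved_s = float(self.windows.total_duration())
        if self.requested_s is not None:
            self.short = self.achieved_s < self.requested_s - 1e-9


def _exclude_bad(windows: IntervalSet, hyp: Hypnogram,
                 include_unscored: bool, label: str) -> IntervalSet:
    """Carve Unsure/Artifact bouts out of plain time windows."""
    if include_unscored or not len(windows):
        return windows
    bad = hyp.bouts_of("Unsure", "Artifact")
    if not len(bad):
        return windows
    lo = min(float(windows.starts.min()), float(bad.starts.min()))
    hi = max(float(windows.ends.max()), float(bad.ends.max()))
    from .intervals import complement

    good = complement(bad, (lo, hi), label="scored")
    return intersect(windows, good, label=label)


def accumulate_state_time(
    bouts: IntervalSet, start: float, quota: float, label: str
) -> ResolvedCondition:
    """First ``quota`` seconds of cumulative bout time at or after ``start``.

    The final bout is truncated mid-bout so the accumulated total is
    exactly the quota; if the bouts run out first the result is returned
    short, with the flag set.
    """
    remaining = quota
    out = []
    for s, e, _ in merge_union(bouts):
        if e <= start:
            continue
        s = max(s, start)
        take = min(e - s, remaining)
        if take > 0:
            out.append((s, s + take, label))
            remaining -= take
        if remaining <= 1e-12:
            break
    return ResolvedCondition(IntervalSet.from_tuples(out), requested_s=quota)


def resolve_condition(
    spec: ConditionSpec, hyp: Hypnogram, include_unscored: bool = False
) -> ResolvedCondition:
    """Resolve a named condition into concrete windows on the session."""
    nrem = hyp.bouts_of("NREM")
    name = spec.name
    if name == "baseline_12h":
        light = IntervalSet.from_arrays(
            [spec.light_onset - DAY], [spec.light_onset - DAY + 12 * 3600.0], "light"
        )
        windows = intersect(nrem, light, label="baseline_12h")
        return ResolvedCondition(windows)
    if name == "sd_first_hour":
        sd_start = spec.light_onset
        win = IntervalSet.from_arrays([sd_start], [sd_start + 3600.0], "sd_first_hour")
        return ResolvedCondition(_exclude_bad(win, hyp, include_unscored, "sd_first_hour"))
    if name == "induction":
        win = IntervalSet.from_arrays(
            [spec.sd_end - INDUCTION_LENGTH], [spec.sd_end], "induction")
        return ResolvedCondition(_exclude_bad(win, hyp, include_unscored, "induction"))

    # recovery-family conditions accumulate NREM after SD end
    rec = accumulate_state_time(nrem, spec.sd_end, 3600.0, "recovery_1h_nrem")
    if name == "recovery_1h_nrem":
        return rec
    if name == "recovery_first_30min":
        half = accumulate_state_time(nrem, spec.sd_end, 1800.0, "recovery_first_30min")
        return half
    if name == "circadian_matched_1h":
        if not len(rec.windows):
            log.warning("no NREM after SD end; circadian-matched window is empty")
            return ResolvedCondition(IntervalSet(), requested_s=3600.0)
        recovery_start = float(rec.windows.starts[0])
        return accumulate_state_time(
            nrem, recovery_start - DAY, 3600.0, "circadian_matched_1h"
        )
    raise AssertionError(f"unhandled condition {name!r}")
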