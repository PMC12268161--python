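"""Stepping-in-place analysis from dual force plates.

Vertical ground-reaction forces (1000 Hz) are normalised to percent body
weight, segmented into gait cycles by an unload-threshold crossing, and
summarised as swing/stride times, asymmetry, arrhythmicity and percent
time freezing.  Freezing is detected as spans with no full stepping
excursion, where a full excursion requires one foot to drop below 15% of
body weight while the other rises above 85%.

Metric definitions:

* asymmetry = 100 * |ln(shorter mean swing time / longer mean swing time)|
* arrhythmicity = mean over legs of 100 * (sd / mean) of stride times
  (sample sd, n-1 denominator)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .signal_io import TimeSeries

__all__ = [
    "ForcePlateTrial",
    "GaitCycleTable",
    "FreezeIntervals",
    "normalize_to_bodyweight",
    "segment_cycles_force",
    "asymmetry",
    "arrhythmicity",
    "detect_freezes_forceplate",
    "percent_time_freezing",
]

UNLOAD_THRESHOLD_PCT = 20.0     # %BW crossing defining foot-off / foot-strike
HYSTERESIS_S = 0.05             # crossings must persist this long
FREEZE_LOW_PCT = 15.0           # full lift-off: force below this...
FREEZE_HIGH_PCT = 85.0          # ...while contralateral exceeds this
MIN_FREEZE_S = 1.0
MERGE_GAP_S = 0.2


@dataclass
class ForcePlateTrial:
    """Left/right vertical force (N) plus body weight."""

    left: TimeSeries
    right: TimeSeries
    body_weight_n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.left.rate != self.right.rate or len(self.left) != len(self.right):
            raise ValueError("plates must share rate and length")
        if self.body_weight_n is not None and self.body_weight_n <= 0:
            raise ValueError("body weight must be positive")

    @property
    def duration_s(self) -> float:
        return self.left.duration


@dataclass
class LegEvents:
    foot_off_s: np.ndarray
    foot_strike_s: np.ndarray
    swing_times_s: np.ndarray
    stride_times_s: np.ndarray


@dataclass
class GaitCycleTable:
    left: LegEvents
    right: LegEvents

    @property
    def n_strides(self) -> int:
        return int(self.left.stride_times_s.size + self.right.stride_times_s.size)


@dataclass
class FreezeIntervals:
    intervals: List[Tuple[float, float]]
    duration_s: float

    @property
    def total_s(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    @property
    def percent_of_trial(self) -> float:
        return 100.0 * self.total_s / self.duration_s if self.duration_s else 0.0


def normalize_to_bodyweight(trial: ForcePlateTrial) -> Tuple[TimeSeries, TimeSeries]:
    """Forces as percent body weight; weight estimated from the mean total
    vertical force when not provided."""
    bw = trial.body_weight_n
    if bw is None:
        if len(trial.left) == 0:
            return trial.left, trial.right
        bw = float(np.mean(trial.left.values + trial.right.values))
    if bw <= 0:
        raise ValueError("body weight must be positive")
    scale = 100.0 / bw
    left = trial.left.with_values(trial.left.values * scale)
    right = trial.right.with_values(trial.right.values * scale)
    return left, right


def _debounced_crossings(values: np.ndarray, rate: float, threshold: float
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """(falling, rising) crossing indices of ``threshold`` that persist for
    at least HYSTERESIS_S; alternation enforced starting from the initial
    loading state."""
    hold = max(1, int(round(HYSTERESIS_S * rate)))
    below = values < threshold
    falls, rises = [], []
    state_below = bool(below[0]) if below.size else False
    i = 1
    n = below.size
    while i < n:
        if below[i] != state_below:
            j = i
            while j < n and below[j] != state_below and j - i < hold:
                j += 1
            if j - i >= hold:
                (falls if not state_below else rises).append(i)
                state_below = not state_below
                i = j
            else:
                i = j
        else:
            i += 1
    return np.asarray(falls, dtype=int), np.asarray(rises, dtype=int)


def _leg_events(pct: TimeSeries) -> LegEvents:
    falls, rises = _debounced_crossings(pct.values, pct.rate, UNLOAD_THRESHOLD_PCT)
    t0, r = pct.start_time, pct.rate
    foot_off = t0 + falls / r
    foot_strike = t0 + rises / r
    swings = []
    for off in foot_off:
        later = foot_strike[foot_strike > off]
        if later.size:
            swings.append(later[0] - off)
    strides = np.diff(foot_strike)
    return LegEvents(foot_off_s=foot_off, foot_strike_s=foot_strike,
                     swing_times_s=np.asarray(swings),
                     stride_times_s=strides)


def segment_cycles_force(left_pct: TimeSeries, right_pct: TimeSeries) -> GaitCycleTable:
    """Gait cycles from %BW traces: foot-off when force drops below the
    unload threshold (20% BW, 50 ms debounce), foot-strike when it rises
    back; swing = off->strike, stride = strike->next strike (same leg)."""
    return GaitCycleTable(left=_leg_events(left_pct), right=_leg_events(right_pct))


def asymmetry(swing_times_left: Sequence[float],
              swing_times_right: Sequence[float]) -> float:
    """100 * |ln(shorter mean swing / longer mean swing)|, in percent."""
    l, r = np.asarray(swing_times_left, float), np.asarray(swing_times_right, float)
    if l.size == 0 or r.size == 0:
        raise UndefinedMetricError("need at least one swing per leg")
    a, b = float(np.mean(l)), float(np.mean(r))
    lo, hi = min(a, b), max(a, b)
    return 100.0 * abs(np.log(lo / hi))


def arrhythmicity(stride_times_left: Sequence[float],
                  stride_times_right: Sequence[float]) -> float:
    """Mean over legs of the stride-time coefficient of variation (%)."""
    cvs = []
    for s in (stride_times_left, stride_times_right):
        s = np.asarray(s, float)
        if s.size < 2:
            raise UndefinedMetricError("need at least two strides per leg")
        cvs.append(100.0 * np.std(s, ddof=1) / np.mean(s))
    return float(np.mean(cvs))


def detect_freezes_forceplate(left_pct: TimeSeries, right_pct: TimeSeries,
                              min_freeze_s: float = MIN_FREEZE_S,
                              low_pct: float = FREEZE_LOW_PCT,
                              high_pct: float = FREEZE_HIGH_PCT,
                              merge_gap_s: float = MERGE_GAP_S) -> FreezeIntervals:
    """Spans without a full stepping excursion on either side.

    A full excursion is any sample where one foot is below ``low_pct`` %BW
    and the other above ``high_pct``; spans of at least ``min_freeze_s``
    containing none are freezes, and freezes separated by short excursion
    blips (< ``merge_gap_s``) merge.
    """
    l, r = left_pct.values, right_pct.values
    rate = left_pct.rate
    duration = left_pct.duration
    excursion = ((l < low_pct) & (r > high_pct)) | ((r < low_pct) & (l > high_pct))
    exc_idx = np.flatnonzero(excursion)
    if exc_idx.size == 0:
        intervals = [(0.0, duration)] if duration >= min_freeze_s else []
        return FreezeIntervals(intervals=intervals, duration_s=duration)
    times = exc_idx / rate
    gaps: List[Tuple[float, float]] = []
    if times[0] >= min_freeze_s:
        gaps.append((0.0, times[0]))
    internal = np.flatnonzero(np.diff(times) >= min_freeze_s)
    for i in internal:
        gaps.append((times[i], times[i + 1]))
    if duration - times[-1] >= min_freeze_s:
        gaps.append((times[-1], duration))
    merged: List[Tuple[float, float]] = []
    for g in gaps:
        if merged and g[0] - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], g[1])
        else:
            merged.append(g)
    return FreezeIntervals(intervals=merged, duration_s=duration)


def percent_time_freezing(intervals: FreezeIntervals,
                          duration_s: Optional[float] = None) -> float:
    """100 * total frozen time / trial duration."""
    duration = duration_s if duration_s is not None else intervals.duration_s
    if duration <= 0:
        raise ValueError("trial duration must be positive")
    for a, b in intervals.intervals:
        if a < -1e-9 or b > duration + 1e-9:
            raise ValueError("freeze interval outside the trial")
    return 100.0 * sum(b - a for a, b in intervals.intervals) / duration
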