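"""Turning-and-barrier-course and wrist analyses from IMU gyroscopes.

Shank pipeline: low-pass each gyroscope axis with a zero-phase 8th-order
Butterworth at 9 Hz, extract the sagittal-plane angular velocity as the
first principal component of the 3-axis signal (sign fixed so swing peaks
are positive), segment strides around mid-swing peaks, and feed rolling
gait features into a logistic regression that flags freezing when the
predicted probability exceeds 0.7.  The model uses arrhythmicity and
asymmetry over the last six steps plus the last step's stride time and
swing angular range; its coefficients are fitted on a labelled corpus.

Wrist pipeline: zero-phase 4th-order Butterworth at 4 Hz, then RMS
angular velocity (bradykinesia) and zero-crossing cycle rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateSignalError,
    InsufficientLengthError,
    UndefinedMetricError,
)
from .gait_kinetics import FreezeIntervals, arrhythmicity, asymmetry
from .signal_io import TimeSeries, design_butter_lowpass, filter_zero_phase

__all__ = [
    "ImuTrial",
    "Stride",
    "StrideTable",
    "FreezeModel",
    "extract_sagittal",
    "segment_strides_imu",
    "mean_peak_shank_angular_velocity",
    "freeze_probability",
    "detect_freezes_logistic",
    "fit_freeze_model",
    "wrist_vrms",
    "wrist_cycles_per_second",
]

SHANK_LOWPASS_HZ = 9.0
SHANK_LOWPASS_ORDER = 8
WRIST_LOWPASS_HZ = 4.0
WRIST_LOWPASS_ORDER = 4
PEAK_FRACTION = 0.4           # of the 95th percentile of positive samples
FEATURE_WINDOW_STEPS = 6
FREEZE_PROBABILITY = 0.7


@dataclass
class ImuTrial:
    """3-axis angular velocity (deg/s) per sensor at 128 Hz."""

    sensors: Dict[str, np.ndarray]      # name -> (n, 3) array
    rate: float = 128.0

    def __post_init__(self) -> None:
        for name, arr in self.sensors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"sensor {name!r} must be (n, 3)")
            self.sensors[name] = arr


@dataclass(frozen=True)
class Stride:
    mid_swing_s: float
    stride_time_s: float
    swing_time_s: float
    swing_range_deg: float
    peak_velocity_deg_s: float
    swing_start_s: float
    swing_end_s: float
    leg: str = ""


@dataclass
class StrideTable:
    strides: List[Stride]
    low_confidence: bool = False

    def __len__(self) -> int:
        return len(self.strides)

    def peaks(self) -> np.ndarray:
        return np.asarray([s.peak_velocity_deg_s for s in self.strides])


def extract_sagittal(gyro_xyz: np.ndarray, rate: float = 128.0) -> Tuple[TimeSeries, float]:
    """Sagittal angular velocity via 9 Hz low-pass + PCA.

    Returns the projected series and the fraction of variance explained by
    the first principal axis (low values mean no dominant rotation plane).
    """
    arr = np.asarray(gyro_xyz, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) gyroscope array")
    if arr.shape[0] < 2 * rate:
        raise InsufficientLengthError("need at least 2 s of gyroscope data")
    spec = design_butter_lowpass(SHANK_LOWPASS_HZ, SHANK_LOWPASS_ORDER, rate)
    filt = np.column_stack([
        filter_zero_phase(TimeSeries(values=arr[:, k], rate=rate), spec).values
        for k in range(3)])
    centered = filt - filt.mean(axis=0)
    cov = centered.T @ centered / max(1, centered.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise DegenerateSignalError("constant gyroscope signal")
    axis = evecs[:, -1]
    proj = centered @ axis
    # fix sign so the dominant swing peaks are positive
    hi = np.percentile(proj, 98)
    lo = np.percentile(proj, 2)
    if abs(lo) > abs(hi):
        proj = -proj
    explained = float(evals[-1] / evals.sum())
    return TimeSeries(values=proj, rate=rate, units="deg/s"), explained


def segment_strides_imu(sagittal: TimeSeries, leg: str = "") -> StrideTable:
    """Strides from sagittal shank angular velocity.

    Mid-swing = positive local maxima above 0.4x the 95th percentile of
    positive samples; the swing spans the nearest zero crossings around
    each mid-swing; swing angular range is the time-integral of angular
    velocity over the swing (degrees); stride time is the interval between
    successive mid-swings of the same leg.
    """
    v = sagittal.values
    rate = sagittal.rate
    pos = v[v > 0]
    if pos.size < 2:
        return StrideTable(strides=[])
    height = PEAK_FRACTION * np.percentile(pos, 95)
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(v, height=height)
    if peaks.size < 2:
        return StrideTable(strides=[])
    # nearest zero crossings (or signal ends) around each peak
    nonpos = v <= 0
    strides: List[Stride] = []
    mids = sagittal.start_time + peaks / rate
    for k, p in enumerate(peaks):
        left = p
        while left > 0 and not nonpos[left - 1]:
            left -= 1
        right = p
        while right < v.size - 1 and not nonpos[right + 1]:
            right += 1
        swing_start = sagittal.start_time + left / rate
        swing_end = sagittal.start_time + right / rate
        seg = v[left:right + 1]
        rng = float(np.trapezoid(seg, dx=1.0 / rate))
        stride_time = float(mids[k] - mids[k - 1]) if k > 0 else np.nan
        strides.append(Stride(mid_swing_s=float(mids[k]),
                              stride_time_s=stride_time,
                              swing_time_s=swing_end - swing_start,
                              swing_range_deg=rng,
                              peak_velocity_deg_s=float(v[p]),
                              swing_start_s=swing_start,
                              swing_end_s=swing_end, leg=leg))
    return StrideTable(strides=strides)


def mean_peak_shank_angular_velocity(tables: Sequence[StrideTable]) -> float:
    """Mean per-stride peak sagittal angular velocity pooled across legs."""
    peaks = np.concatenate([t.peaks() for t in tables]) if tables else np.empty(0)
    if peaks.size == 0:
        raise UndefinedMetricError("no strides detected")
    return float(np.mean(peaks))


# ---------------------------------------------------------------------------
# Logistic freeze model.

@dataclass
class FreezeModel:
    """Logistic freeze-probability model over per-step gait features.

    Features, in order: arrhythmicity over the last six steps (%),
    asymmetry over the last six steps (%), last stride time (s), last
    swing angular range (deg).  Inputs are standardised with the stored
    means/sds before applying the logistic.
    """

    beta0: float
    betas: np.ndarray               # 4 weights
    feature_means: np.ndarray
    feature_sds: np.ndarray
    probability_threshold: float = FREEZE_PROBABILITY
    holdout_auroc: Optional[float] = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability threshold must lie in (0, 1)")


FEATURE_NAMES = ("arrhythmicity_6", "asymmetry_6", "stride_time_last",
                 "swing_range_last")


def freeze_probability(features: Sequence[float], model: FreezeModel) -> float:
    """p = logistic(beta0 + betas . standardized features)."""
    x = np.asarray(features, dtype=float)
    if x.shape != (4,) or not np.all(np.isfinite(x)):
        raise ValueError("need four finite features")
    z = (x - model.feature_means) / model.feature_sds
    return float(1.0 / (1.0 + np.exp(-(model.beta0 + model.betas @ z))))


def step_features(tables: Sequence[StrideTable],
                  window: int = FEATURE_WINDOW_STEPS) -> Tuple[List[Stride], np.ndarray]:
    """Per-step rolling features over steps pooled across legs.

    Steps are ordered by mid-swing time; the first ``window`` steps carry
    no feature row (NaN).  When a window lacks two strides on a leg the
    previous arrhythmicity/asymmetry values carry forward.
    """
    steps = sorted((s for t in tables for s in t.strides),
                   key=lambda s: s.mid_swing_s)
    n = len(steps)
    feats = np.full((n, 4), np.nan)
    prev_arr, prev_asym = np.nan, np.nan
    for i in range(n):
        if i + 1 < window:
            continue
        win = steps[i + 1 - window:i + 1]
        legs = {s.leg for s in win}
        arr_val, asym_val = prev_arr, prev_asym
        if len(legs) >= 2:
            by_leg = {leg: [s for s in win if s.leg == leg] for leg in legs}
            stride_groups = [[s.stride_time_s for s in grp
                              if np.isfinite(s.stride_time_s)]
                             for grp in by_leg.values()]
            swing_groups = [[s.swing_time_s for s in grp] for grp in by_leg.values()]
            try:
                arr_val = arrhythmicity(*stride_groups[:2])
            except UndefinedMetricError:
                pass
            try:
                asym_val = asymmetry(*swing_groups[:2])
            except UndefinedMetricError:
                pass
        last = steps[i]
        stride_t = last.stride_time_s
        if not np.isfinite(stride_t):
            stride_t = np.nan
        feats[i] = (arr_val, asym_val, stride_t, last.swing_range_deg)
        prev_arr, prev_asym = arr_val, asym_val
    return steps, feats


def detect_freezes_logistic(tables: Sequence[StrideTable], model: FreezeModel
                            ) -> FreezeIntervals:
    """Freeze intervals: contiguous steps with p > threshold.

    Each interval runs from the first suprathreshold step's swing start to
    the last one's swing end.  Fewer than window+1 steps yields no
    intervals.
    """
    steps, feats = step_features(tables)
    if not steps:
        return FreezeIntervals(intervals=[], duration_s=0.0)
    duration = max(s.swing_end_s for s in steps)
    if len(steps) < FEATURE_WINDOW_STEPS + 1:
        return FreezeIntervals(intervals=[], duration_s=duration)
    intervals: List[Tuple[float, float]] = []
    open_start: Optional[float] = None
    last_end = 0.0
    for step, row in zip(steps, feats):
        if not np.all(np.isfinite(row)):
            continue
        p = freeze_probability(row, model)
        if p > model.probability_threshold:
            if open_start is None:
                open_start = step.swing_start_s
            last_end = step.swing_end_s
        elif open_start is not None:
            intervals.append((open_start, last_end))
            open_start = None
    if open_start is not None:
        intervals.append((open_start, last_end))
    return FreezeIntervals(intervals=intervals, duration_s=duration)


def fit_freeze_model(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                     holdout_fraction: float = 0.3,
                     probability_threshold: float = FREEZE_PROBABILITY
                     ) -> FreezeModel:
    """Fit the logistic freeze model by maximum likelihood.

    Features are standardised; discrimination is reported as AUROC on a
    held-out split.  Both classes must be present.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("features must be (n, 4)")
    if len(np.unique(y)) < 2:
        raise ValueError("both freeze and non-freeze steps required")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    Ztr, Zte, ytr, yte = train_test_split(Z, y, test_size=holdout_fraction,
                                          random_state=seed, stratify=y)
    clf = LogisticRegression(max_iter=2000).fit(Ztr, ytr)
    auroc = float(roc_auc_score(yte, clf.predict_proba(Zte)[:, 1]))
    return FreezeModel(beta0=float(clf.intercept_[0]),
                       betas=clf.coef_[0].copy(),
                       feature_means=means, feature_sds=sds,
                       probability_threshold=probability_threshold,
                       holdout_auroc=auroc)


# ---------------------------------------------------------------------------
# Wrist flexion-extension (bradykinesia).

def _filter_wrist(series: TimeSeries) -> TimeSeries:
    spec = design_butter_lowpass(WRIST_LOWPASS_HZ, WRIST_LOWPASS_ORDER, series.rate)
    return filter_zero_phase(series, spec)


def wrist_vrms(hand: TimeSeries, min_duration_s: float = 5.0) -> float:
    """RMS of the 4 Hz low-passed flexion-extension angular velocity."""
    if hand.duration < min_duration_s:
        raise InsufficientLengthError(f"need at least {min_duration_s} s")
    return float(np.sqrt(np.mean(_filter_wrist(hand).values ** 2)))


def wrist_cycles_per_second(hand: TimeSeries, min_duration_s: float = 5.0) -> float:
    """Flexion-extension cycle rate: positive-going zero crossings of the
    demeaned, 4 Hz low-passed signal divided by the trial duration."""
    if hand.duration < min_duration_s:
        raise InsufficientLengthError(f"need at least {min_duration_s} s")
    v = _filter_wrist(hand).values
    v = v - v.mean()
    crossings = np.count_nonzero((v[:-1] <= 0) & (v[1:] > 0))
    return crossings / hand.duration
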