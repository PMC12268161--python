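"""Beta burst detection from subthalamic LFP.

Pipeline (identical offline and streaming): bandpass the LFP with a
128-order FIR around a participant-specific 6 Hz band inside the beta
range (13-30 Hz), square the filtered signal, locate the local maxima of
the squared signal and linearly interpolate between them to form the beta
envelope.  Bursts are maximal runs of the envelope above a power
threshold; the power threshold is the mean of the trough (local-minimum)
values of the same envelope computed in the 45-65 Hz band on an
OFF-stimulation recording.  The controller consumes the "current burst
duration": the ongoing suprathreshold period if one is active, otherwise
the most recently completed one.

The streaming detector is sample-exact with the offline path for any
chunking of the input (outside the FIR warm-up), and supports blanking of
stimulation-change artifacts: samples inside a blanked span are excluded
from burst logic, and a burst that is ongoing when a blank begins is held
until the first post-blank sample decides whether it continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InsufficientLengthError,
    StreamError,
)
from .signal_io import TimeSeries, design_fir_bandpass

__all__ = [
    "BandConfig",
    "EnvelopeSeries",
    "BurstEvent",
    "BurstThresholds",
    "BurstDetector",
    "compute_envelope",
    "power_threshold_from_gamma",
    "extract_bursts",
    "mean_burst_duration",
]

BETA_RANGE_HZ = (13.0, 30.0)
GAMMA_BAND_HZ = (45.0, 65.0)
FIR_ORDER = 128


@dataclass(frozen=True)
class BandConfig:
    """Detection band: centre frequency and width (default 6 Hz)."""

    center_hz: float
    width_hz: float = 6.0

    def __post_init__(self) -> None:
        if self.width_hz <= 0:
            raise ValueError("band width must be positive")

    @property
    def edges(self) -> Tuple[float, float]:
        return (self.center_hz - self.width_hz / 2.0,
                self.center_hz + self.width_hz / 2.0)


@dataclass
class EnvelopeSeries:
    """Squared-peak interpolated envelope of a band-filtered signal."""

    series: TimeSeries
    band: BandConfig

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def rate(self) -> float:
        return self.series.rate


@dataclass(frozen=True)
class BurstEvent:
    """One suprathreshold envelope episode."""

    onset_s: float
    offset_s: float
    ongoing: bool = False

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class BurstThresholds:
    """Power threshold (envelope units) + duration threshold (seconds)."""

    power_threshold: float
    duration_threshold_s: float

    def __post_init__(self) -> None:
        if self.power_threshold <= 0 or self.duration_threshold_s <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# Plateau-aware extrema of a sampled sequence.

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a flat plateau yields its last sample.

    A sample is a maximum when the last preceding non-flat step was a rise
    and the next step is a fall.  Endpoints are never maxima.
    """
    if x.size < 3:
        return np.empty(0, dtype=int)
    d = np.sign(np.diff(x))
    nz = d != 0
    idx = np.where(nz, np.arange(d.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, d[np.clip(idx, 0, None)], 0.0)
    mask = (filled[:-1] > 0) & (d[1:] < 0)
    return np.flatnonzero(mask) + 1


class _EnvelopeStream:
    """Incremental squared-peak interpolation with exact chunk invariance.

    Consumes raw LFP samples; emits envelope samples on the same grid.
    Envelope values between consecutive maxima of the squared band-passed
    signal are linear interpolations of the two peak values; samples before
    the first (after the last) maximum hold the nearest peak value.
    Emission lags the input by up to one inter-peak interval.
    """

    def __init__(self, band: BandConfig, rate: float, order: int = FIR_ORDER):
        spec = design_fir_bandpass(band.center_hz, band.width_hz, order, rate)
        self.band = band
        self.rate = rate
        self._b = spec.b
        self._zi = np.zeros(len(spec.b) - 1)
        self._carry_val: Optional[float] = None   # last squared sample
        self._carry_sign = 0.0                    # last non-flat step sign
        self._n_in = 0                            # raw samples consumed
        self._last_max: Optional[Tuple[int, float]] = None
        self._n_emitted = 0

    def update(self, samples: np.ndarray) -> Tuple[int, np.ndarray]:
        """Feed raw samples; return (start_index, new envelope samples)."""
        samples = np.asarray(samples, dtype=float)
        start = self._n_emitted
        if samples.size == 0:
            return start, np.empty(0)
        y, self._zi = sps.lfilter(self._b, [1.0], samples, zi=self._zi)
        sq = y * y
        if self._carry_val is not None:
            s = np.concatenate(([self._carry_val], sq))
            base = self._n_in - 1
        else:
            s = sq
            base = self._n_in
        self._n_in += samples.size

        out: List[np.ndarray] = []
        if s.size >= 2:
            d = np.sign(np.diff(s))
            nz = d != 0
            idx = np.where(nz, np.arange(d.size), -1)
            np.maximum.accumulate(idx, out=idx)
            filled = np.where(idx >= 0, d[np.clip(idx, 0, None)], self._carry_sign)
            # sample p is a peak when the last non-flat step before it rose
            # and the step after it falls; p == 0 uses the carried slope sign
            pre = np.concatenate(([self._carry_sign], filled[:-1]))
            mask = (pre > 0) & (d < 0)
            for j in np.flatnonzero(mask):
                self._emit_to(base + int(j), float(s[j]), out)
            self._carry_sign = float(filled[-1])
        self._carry_val = float(s[-1])
        env = np.concatenate(out) if out else np.empty(0)
        self._n_emitted += env.size
        return start, env

    def _emit_to(self, j: int, vj: float, out: List[np.ndarray]) -> None:
        n0 = self._n_emitted + sum(a.size for a in out)
        if self._last_max is None:
            out.append(np.full(j - n0 + 1, vj))
        else:
            i, vi = self._last_max
            frac = (np.arange(n0, j + 1) - i) / (j - i)
            out.append(vi + frac * (vj - vi))
        self._last_max = (j, vj)

    def finalize(self) -> Tuple[int, np.ndarray]:
        """Flush: hold the last maximum value to the end of the input."""
        start = self._n_emitted
        if self._last_max is None:
            return start, np.empty(0)
        n = self._n_in - self._n_emitted
        self._n_emitted = self._n_in
        return start, np.full(n, self._last_max[1])


def compute_envelope(lfp: TimeSeries, band: BandConfig,
                     order: int = FIR_ORDER) -> EnvelopeSeries:
    """Offline beta/gamma envelope (causal FIR -> square -> peak interp)."""
    if lfp.rate < 4.0 * band.edges[1]:
        raise ValueError("sampling rate too low for the requested band")
    if len(lfp) <= 3 * order:
        raise InsufficientLengthError("LFP shorter than 3x FIR order")
    stream = _EnvelopeStream(band, lfp.rate, order)
    _, head = stream.update(lfp.values)
    _, tail = stream.finalize()
    env = np.concatenate([head, tail])
    if env.size != len(lfp) or stream._last_max is None:
        raise DegenerateSignalError("no peaks found in squared signal")
    ts = TimeSeries(values=env, rate=lfp.rate, start_time=lfp.start_time,
                    units=f"({lfp.units})^2" if lfp.units else "",
                    label=f"envelope[{band.center_hz:g}Hz]")
    return EnvelopeSeries(series=ts, band=band)


def power_threshold_from_gamma(off_lfp: TimeSeries, min_duration_s: float = 10.0,
                               order: int = FIR_ORDER) -> float:
    """Power threshold: mean trough of the 45-65 Hz envelope OFF stimulation."""
    if off_lfp.duration < min_duration_s:
        raise InsufficientLengthError(
            f"OFF recording shorter than {min_duration_s} s")
    lo, hi = GAMMA_BAND_HZ
    band = BandConfig(center_hz=(lo + hi) / 2.0, width_hz=hi - lo)
    env = compute_envelope(off_lfp, band, order=order)
    warm = order  # skip FIR warm-up
    minima = _local_maxima(-env.values[warm:])
    if minima.size < 10:
        raise InsufficientDataError("fewer than 10 envelope troughs")
    return float(np.mean(env.values[warm:][minima]))


def extract_bursts(env: EnvelopeSeries, power_threshold: float) -> List[BurstEvent]:
    """Maximal runs of envelope > threshold, at sample resolution."""
    if power_threshold <= 0:
        raise ValueError("power threshold must be positive")
    above = env.values > power_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.concatenate(([0], onsets))
    t0, r = env.series.start_time, env.rate
    events = [BurstEvent(onset_s=t0 + i / r, offset_s=t0 + j / r)
              for i, j in zip(onsets, offsets)]
    if above[-1]:
        events.append(BurstEvent(onset_s=t0 + onsets[-1] / r,
                                 offset_s=t0 + above.size / r, ongoing=True))
    return events


def mean_burst_duration(events: List[BurstEvent],
                        include_ongoing: bool = False) -> float:
    """Arithmetic mean duration of (completed) bursts."""
    durs = [e.duration_s for e in events if include_ongoing or not e.ongoing]
    if not durs:
        raise InsufficientDataError("no completed bursts")
    return float(np.mean(durs))


# ---------------------------------------------------------------------------
# Streaming detector with blanking.

@dataclass
class _Blank:
    start_idx: int
    end_idx: int


@dataclass
class BurstDetector:
    """Streaming burst detector for one hemisphere.

    Feed raw LFP chunks with :meth:`process`; completed bursts are returned
    as they are resolved and the controller-facing
    :meth:`current_burst_duration` reflects the most recent suprathreshold
    period in the (default 5 s) buffer.
    """

    band: BandConfig
    power_threshold: float
    rate: float = 500.0
    capacity_s: float = 5.0
    order: int = FIR_ORDER
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.power_threshold <= 0:
            raise ValueError("power threshold must be positive")
        self._stream = _EnvelopeStream(self.band, self.rate, self.order)
        self._blanks: List[_Blank] = []
        self._in_burst = False
        self._onset_idx = 0
        self._held_at_blank: Optional[int] = None  # blank start idx, burst held
        self._last_completed: Optional[Tuple[int, int]] = None
        self._n_env = 0  # envelope samples consumed by burst logic

    # -- time/index helpers
    def _t(self, idx: int) -> float:
        return self.start_time + idx / self.rate

    @property
    def samples_seen(self) -> int:
        return self._stream._n_in

    # -- blanking
    def blank_interval(self, start_s: float, duration_s: float) -> None:
        """Exclude [start, start+duration) from burst logic."""
        if duration_s < 0:
            raise ValueError("blank duration must be >= 0")
        if duration_s == 0:
            return
        i0 = int(np.floor((start_s - self.start_time) * self.rate))
        i1 = int(np.ceil((start_s + duration_s - self.start_time) * self.rate))
        self._blanks.append(_Blank(start_idx=i0, end_idx=i1))

    def _blank_of(self, idx: int) -> Optional[_Blank]:
        for b in self._blanks:
            if b.start_idx <= idx < b.end_idx:
                return b
        return None

    # -- main entry
    def process(self, samples: np.ndarray) -> List[BurstEvent]:
        """Consume a raw LFP chunk; return bursts completed by it."""
        samples = np.asarray(samples, dtype=float)
        start, env = self._stream.update(samples)
        return self._consume(start, env)

    def flush(self) -> List[BurstEvent]:
        """Flush the envelope tail (end of recording)."""
        start, env = self._stream.finalize()
        events = self._consume(start, env)
        if self._in_burst:
            events.append(BurstEvent(onset_s=self._t(self._onset_idx),
                                     offset_s=self._t(self._n_env), ongoing=True))
        return events

    def _consume(self, start: int, env: np.ndarray) -> List[BurstEvent]:
        events: List[BurstEvent] = []
        thr = self.power_threshold
        for k in range(env.size):
            idx = start + k
            blank = self._blank_of(idx)
            if blank is not None:
                if self._in_burst and self._held_at_blank is None:
                    self._held_at_blank = blank.start_idx
                continue
            above = env[k] > thr
            if self._in_burst:
                if above:
                    self._held_at_blank = None
                else:
                    offset = (self._held_at_blank
                              if self._held_at_blank is not None else idx)
                    events.append(BurstEvent(onset_s=self._t(self._onset_idx),
                                             offset_s=self._t(offset)))
                    self._last_completed = (self._onset_idx, offset)
                    self._in_burst = False
                    self._held_at_blank = None
            elif above:
                self._in_burst = True
                self._onset_idx = idx
        self._n_env = start + env.size
        # drop blanks that can no longer matter
        self._blanks = [b for b in self._blanks if b.end_idx > self._n_env
                        or self._held_at_blank == b.start_idx]
        return events

    # -- controller-facing state
    def current_burst_duration(self, now_s: Optional[float] = None) -> float:
        """Duration (s) of the most recent suprathreshold period.

        Ongoing burst: elapsed time since its onset (frozen at the blank
        start while a blank is undecided).  Otherwise the duration of the
        most recently completed burst still inside the buffer, else 0.
        """
        if self._n_env == 0 and not self._in_burst:
            raise StreamError("empty buffer")
        if now_s is None:
            now_s = self._t(self._n_env)
        if self._in_burst:
            end = (self._t(self._held_at_blank)
                   if self._held_at_blank is not None else now_s)
            return max(0.0, end - self._t(self._onset_idx))
        if self._last_completed is not None:
            onset, offset = self._last_completed
            if now_s - self._t(offset) <= self.capacity_s:
                return self._t(offset) - self._t(onset)
        return 0.0


def stream_process(detector: BurstDetector,
                   new_samples: np.ndarray) -> Tuple[BurstDetector, List[BurstEvent]]:
    """Functional wrapper over :meth:`BurstDetector.process`."""
    return detector, detector.process(new_samples)
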