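"""Shared DSP primitives and time-series file I/O.

The carriers here (:class:`TimeSeries`, :class:`MultiChannelSeries`) hold
every streamed signal in the package: subthalamic LFP at 500 Hz, vertical
ground-reaction forces at 1000 Hz, and shank/hand gyroscope channels at
128 Hz.  The filters mirror the processing chains used on those signals:
a 128-order bandpass FIR for the LFP beta/gamma envelopes and zero-phase
Butterworth low-passes for the kinematic channels, plus Welch spectral
estimation (1-s Hann window, 50% overlap) for calibration spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import FormatError, InsufficientLengthError, InvalidBandError

__all__ = [
    "TimeSeries",
    "MultiChannelSeries",
    "FilterSpec",
    "Psd",
    "design_fir_bandpass",
    "design_butter_lowpass",
    "filter_zero_phase",
    "welch_psd",
    "read_timeseries_csv",
    "write_timeseries_csv",
]


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values; must be finite.
    rate : float
        Sampling rate in Hz (> 0).
    start_time : float
        Time of the first sample in seconds.
    units, label : str
        Free-text annotations.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class MultiChannelSeries:
    """Named channels sharing one clock (equal rate, start and length)."""

    channels: Dict[str, TimeSeries]
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channels:
            ref = next(iter(self.channels.values()))
            for ts in self.channels.values():
                if ts.rate != ref.rate or len(ts) != len(ref):
                    raise ValueError("channels must share rate and length")

    @property
    def rate(self) -> float:
        return next(iter(self.channels.values())).rate

    def __getitem__(self, name: str) -> TimeSeries:
        return self.channels[name]

    def names(self) -> Tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class FilterSpec:
    """A designed filter: FIR bandpass or Butterworth low-pass."""

    kind: str  # "fir_bandpass" | "butter_lowpass"
    order: int
    band: Tuple[float, float] | float
    rate: float
    zero_phase: bool = False
    b: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    a: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def design_fir_bandpass(center_hz: float, width_hz: float, order: int, rate: float) -> FilterSpec:
    """Design a linear-phase windowed-sinc (Hamming) bandpass FIR.

    ``order + 1`` coefficients; the response is normalised to unity gain at
    the passband centre.  Default use is the 128-order design around a 6 Hz
    band for the beta envelope and around 45-65 Hz for the gamma reference.
    """
    lo, hi = center_hz - width_hz / 2.0, center_hz + width_hz / 2.0
    nyq = rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise InvalidBandError(f"band [{lo}, {hi}] Hz outside (0, {nyq}) Hz")
    if order < 1 or order % 2:
        raise ValueError("FIR order must be a positive even integer")
    b = sps.firwin(order + 1, [lo, hi], fs=rate, pass_zero=False, window="hamming")
    return FilterSpec(kind="fir_bandpass", order=order, band=(lo, hi), rate=rate,
                      zero_phase=False, b=b, a=np.ones(1))


def design_butter_lowpass(cutoff_hz: float, order: int, rate: float) -> FilterSpec:
    """Butterworth low-pass meant for zero-phase (forward-backward) use."""
    if not (0.0 < cutoff_hz < rate / 2.0):
        raise InvalidBandError(f"cutoff {cutoff_hz} Hz outside (0, {rate / 2}) Hz")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=rate)
    return FilterSpec(kind="butter_lowpass", order=order, band=cutoff_hz, rate=rate,
                      zero_phase=True, b=b, a=a)


def filter_zero_phase(series: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Forward-backward filtering: no net phase shift, squared magnitude.

    Uses reflect padding of 3x the filter order to suppress edge
    transients on short trials.
    """
    if spec.rate != series.rate:
        raise ValueError("filter designed for a different rate")
    pad = 3 * spec.order
    if len(series) <= pad:
        raise InsufficientLengthError(
            f"need more than {pad} samples for zero-phase order {spec.order}")
    out = sps.filtfilt(spec.b, spec.a, series.values, padtype="even", padlen=pad)
    return series.with_values(out)


@dataclass
class Psd:
    """One-sided Welch power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray
    window_s: float = 1.0
    overlap_fraction: float = 0.5

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Integrated power over [lo, hi] Hz (trapezoidal)."""
        m = (self.frequencies >= lo_hz) & (self.frequencies <= hi_hz)
        return float(np.trapezoid(self.power[m], self.frequencies[m]))


def welch_psd(series: TimeSeries, window_s: float = 1.0, overlap: float = 0.5) -> Psd:
    """Welch PSD with a Hann window; defaults 1 s window / 50% overlap."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nper = int(round(window_s * series.rate))
    if len(series) < 2 * nper:
        raise InsufficientLengthError("series shorter than two Welch windows")
    f, p = sps.welch(series.values, fs=series.rate, window="hann",
                     nperseg=nper, noverlap=int(round(nper * overlap)))
    return Psd(frequencies=f, power=p, window_s=window_s, overlap_fraction=overlap)


# ---------------------------------------------------------------------------
# CSV I/O.  One dialect: comma-separated, UTF-8, header row required,
# optional leading time column named "time_s".

_TIME_COL = "time_s"
_JITTER_S = 1e-6


def write_timeseries_csv(series: MultiChannelSeries | TimeSeries, path) -> None:
    import pandas as pd

    if isinstance(series, TimeSeries):
        series = MultiChannelSeries(channels={series.label or "ch0": series})
    cols = {}
    if series.channels:
        first = next(iter(series.channels.values()))
        cols[_TIME_COL] = first.times()
    for name, ts in series.channels.items():
        cols[name] = ts.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_timeseries_csv(path, rate: Optional[float] = None) -> MultiChannelSeries:
    import pandas as pd

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("missing header row") from exc
    names = [c for c in df.columns if c != _TIME_COL]
    if not names:
        raise FormatError("no data columns")
    if _TIME_COL in df.columns:
        t = df[_TIME_COL].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or np.ptp(dt) > _JITTER_S:
                raise FormatError("non-uniform or non-monotone timestamps")
            rate = 1.0 / float(np.median(dt))
        elif rate is None:
            rate = 1.0
        start = float(t[0]) if t.size else 0.0
    else:
        if rate is None:
            raise FormatError("no time column and no rate declared")
        start = 0.0
    channels = {
        name: TimeSeries(values=df[name].to_numpy(dtype=float), rate=rate,
                         start_time=start, label=name)
        for name in names
    }
    return MultiChannelSeries(channels=channels)
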