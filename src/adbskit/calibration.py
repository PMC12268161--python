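"""Controller calibration from stimulation titrations.

Titration runs span 25-125% of the clinical amplitude.  From them the
pipeline derives, per hemisphere: the 6 Hz detection band around the beta
peak whose burst durations shorten most with stimulation, the power
threshold (45-65 Hz envelope trough mean, OFF recording), the initial
duration threshold (mean OFF / I_min burst duration), and the therapeutic
window [I_min, I_max] from a behavioural metric (percent time freezing),
capped at 125% of clinical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import burst as bd
from .burst import BandConfig, BurstThresholds
from .controller import TherapeuticWindow
from .errors import InsufficientDataError, NoPeakError, NoWindowError
from .signal_io import Psd, TimeSeries, welch_psd

__all__ = [
    "TitrationRun",
    "CalibrationResult",
    "titration_spectra",
    "find_beta_peaks",
    "select_beta_band",
    "initial_duration_threshold",
    "burst_modulation",
    "select_therapeutic_window",
    "calibrate_hemisphere",
]

BETA_LO, BETA_HI = bd.BETA_RANGE_HZ
_FIT_LO, _FIT_HI = 5.0, 45.0     # 1/f background fit range (beta excluded)
_PEAK_DB = 3.0                   # prominence above the 1/f fit


@dataclass
class TitrationRun:
    """One titration level: LFP + behaviour at a fixed amplitude."""

    amplitude_ma: float
    amplitude_pct: float            # percent of clinical, 0 for OFF
    lfp: TimeSeries
    behavior: Optional[float] = None   # e.g. percent time freezing, in [0, 100]
    side_effect: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_pct <= 125.0 + 1e-9):
            raise ValueError("amplitude must lie in [0, 125]% of clinical")


@dataclass
class CalibrationResult:
    """Per-hemisphere controller parameters produced by calibration."""

    band: Optional[BandConfig]
    thresholds: Optional[BurstThresholds]
    modulation_slope_s_per_ma: Optional[float]
    usable: bool
    reason: str = ""                # "artifact" | "insufficient modulation" | ""
    window: Optional[TherapeuticWindow] = None


def titration_spectra(runs: Sequence[TitrationRun]) -> List[Psd]:
    """Welch PSD (1 s Hann, 50% overlap) per run, ordered by amplitude."""
    if len(runs) < 2:
        raise InsufficientDataError("need at least two titration levels")
    ordered = sorted(runs, key=lambda r: r.amplitude_ma)
    return [welch_psd(r.lfp) for r in ordered]


def find_beta_peaks(psd: Psd) -> List[float]:
    """Beta-range spectral peaks rising >= 3 dB above the 1/f background.

    The background is a log-log linear fit over 5-45 Hz excluding the
    13-30 Hz beta range.
    """
    f, p = psd.frequencies, psd.power
    fit_mask = (f >= _FIT_LO) & (f <= _FIT_HI) & ~((f >= BETA_LO) & (f <= BETA_HI))
    if fit_mask.sum() < 3 or np.any(p[fit_mask] <= 0):
        raise NoPeakError("cannot fit 1/f background")
    coef = np.polyfit(np.log10(f[fit_mask]), np.log10(p[fit_mask]), 1)
    centers: List[float] = []
    beta = np.flatnonzero((f >= BETA_LO) & (f <= BETA_HI))
    for i in beta:
        if i == 0 or i == f.size - 1 or p[i] <= 0:
            continue
        if p[i] > p[i - 1] and p[i] >= p[i + 1]:
            fit_db = 10.0 * np.polyval(coef, np.log10(f[i]))
            if 10.0 * np.log10(p[i]) - fit_db >= _PEAK_DB:
                centers.append(float(f[i]))
    if not centers:
        raise NoPeakError("no beta peak above the 1/f background")
    return centers


def _mean_duration(lfp: TimeSeries, band: BandConfig, power_threshold: float,
                   min_bursts: int = 1) -> float:
    env = bd.compute_envelope(lfp, band)
    warm = bd.FIR_ORDER
    trimmed = bd.EnvelopeSeries(series=TimeSeries(
        values=env.values[warm:], rate=env.rate,
        start_time=env.series.start_time + warm / env.rate), band=band)
    events = [e for e in bd.extract_bursts(trimmed, power_threshold) if not e.ongoing]
    if len(events) < min_bursts:
        raise InsufficientDataError("too few completed bursts")
    return float(np.mean([e.duration_s for e in events]))


def burst_modulation(runs: Sequence[TitrationRun], band: BandConfig,
                     power_threshold: float) -> Tuple[Dict[float, float], float]:
    """Mean burst duration per amplitude and its least-squares slope (s/mA)."""
    if len(runs) < 3:
        raise InsufficientDataError("need at least three amplitude levels")
    by_amp: Dict[float, float] = {}
    for r in sorted(runs, key=lambda r: r.amplitude_ma):
        by_amp[r.amplitude_ma] = _mean_duration(r.lfp, band, power_threshold)
    amps = np.array(list(by_amp))
    durs = np.array([by_amp[a] for a in amps])
    slope = float(np.polyfit(amps, durs, 1)[0])
    return by_amp, slope


def select_beta_band(runs: Sequence[TitrationRun], power_threshold: float,
                     width_hz: float = 6.0) -> Tuple[BandConfig, float]:
    """Choose the candidate beta peak whose burst durations shorten most
    with stimulation; returns (band, slope in s/mA)."""
    off = min(runs, key=lambda r: r.amplitude_ma)
    peaks = find_beta_peaks(welch_psd(off.lfp))
    best: Optional[Tuple[BandConfig, float]] = None
    for center in peaks:
        band = BandConfig(center_hz=center, width_hz=width_hz)
        try:
            _, slope = burst_modulation(runs, band, power_threshold)
        except InsufficientDataError:
            continue
        if best is None or slope < best[1]:
            best = (band, slope)
    if best is None:
        raise NoPeakError("no candidate band produced enough bursts")
    return best


def initial_duration_threshold(run: TitrationRun, band: BandConfig,
                               power_threshold: float,
                               min_bursts: int = 10) -> float:
    """Initial duration threshold: mean burst duration OFF or at I_min."""
    return _mean_duration(run.lfp, band, power_threshold, min_bursts=min_bursts)


def default_benefit_rule(behavior: float, off_behavior: float) -> bool:
    """Acceptable benefit: metric halved vs OFF, or down by 50 points."""
    return behavior <= 0.5 * off_behavior or behavior < off_behavior - 50.0


def default_tolerance_rule(behavior: float, best_behavior: float) -> bool:
    """Not worse than the best level by more than 10 points."""
    return behavior <= best_behavior + 10.0


def select_therapeutic_window(
    runs: Sequence[TitrationRun], clinical_ma: float,
    benefit_rule: Callable[[float, float], bool] = default_benefit_rule,
    tolerance_rule: Callable[[float, float], bool] = default_tolerance_rule,
    i_min_floor_ma: float = 0.0,
) -> TherapeuticWindow:
    """I_min: lowest amplitude with acceptable benefit vs OFF; I_max:
    highest amplitude without side effects whose behaviour stays within
    tolerance of the best level; capped at 125% of clinical."""
    ordered = sorted(runs, key=lambda r: r.amplitude_ma)
    if any(r.behavior is None for r in ordered):
        raise ValueError("every titration run needs a behaviour metric")
    off = ordered[0]
    cap = 1.25 * clinical_ma
    stim = [r for r in ordered if r.amplitude_ma > 0 and r.amplitude_ma <= cap + 1e-9]
    i_min = None
    for r in stim:
        if benefit_rule(r.behavior, off.behavior) and r.amplitude_ma >= i_min_floor_ma:
            i_min = r.amplitude_ma
            break
    if i_min is None:
        raise NoWindowError("no amplitude satisfies the benefit rule")
    eligible = [r for r in stim if r.amplitude_ma >= i_min and not r.side_effect]
    best = min(r.behavior for r in eligible)
    i_max = i_min
    for r in eligible:
        if tolerance_rule(r.behavior, best):
            i_max = max(i_max, r.amplitude_ma)
    return TherapeuticWindow(i_min_ma=i_min, i_max_ma=min(i_max, cap),
                             clinical_ma=clinical_ma)


def calibrate_hemisphere(runs: Sequence[TitrationRun], clinical_ma: float,
                         min_bursts: int = 10,
                         with_window: bool = True) -> CalibrationResult:
    """End-to-end calibration of one hemisphere from titration runs."""
    off = min(runs, key=lambda r: r.amplitude_ma)
    power_thr = bd.power_threshold_from_gamma(off.lfp)
    try:
        band, slope = select_beta_band(runs, power_thr)
    except NoPeakError:
        return CalibrationResult(band=None, thresholds=None,
                                 modulation_slope_s_per_ma=None,
                                 usable=False, reason="insufficient modulation")
    window = None
    if with_window and all(r.behavior is not None for r in runs):
        window = select_therapeutic_window(runs, clinical_ma)
    # initial duration threshold from the run at (or nearest) I_min when a
    # window is known, otherwise from the OFF run
    source = off
    if window is not None:
        source = min(runs, key=lambda r: abs(r.amplitude_ma - window.i_min_ma))
    dur_thr = initial_duration_threshold(source, band, power_thr,
                                         min_bursts=min_bursts)
    return CalibrationResult(
        band=band,
        thresholds=BurstThresholds(power_threshold=power_thr,
                                   duration_threshold_s=dur_thr),
        modulation_slope_s_per_ma=slope, usable=True, window=window)
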