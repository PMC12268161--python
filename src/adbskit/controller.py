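"""Single-threshold adaptive stimulation control.

The policy: each decision period, compare the current beta burst duration
with a participant-specific duration threshold and increment stimulation
by one 0.1 mA step when the burst is longer, decrement when it is shorter
(ties decrement).  Steps are rate-limited to 0.1 mA/s up and 0.05 mA/s
down (down always half of up, biasing stimulation up) and clamped to the
therapeutic window [I_min, I_max], which never exceeds 125% of the
clinical amplitude.  Stimulation constants — 140.1 Hz, 60 us pulse width
— are fixed across conditions.

Also provided: the constant-amplitude (cDBS) condition, the randomly
adapting control condition (rDBS) built by shuffling the adaptation
pattern of a completed adaptive run so total electrical energy delivered
(TEED) is preserved, and a unit-impedance TEED proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .burst import BandConfig, BurstDetector, BurstEvent, BurstThresholds
from .errors import AdbsKitError
from .signal_io import TimeSeries

__all__ = [
    "STIM_FREQUENCY_HZ",
    "STIM_PULSE_WIDTH_S",
    "TherapeuticWindow",
    "RampPolicy",
    "HemisphereConfig",
    "ControllerState",
    "StimTrace",
    "AdaptationPattern",
    "Decision",
    "decide",
    "apply_step",
    "run_adaptive",
    "hold_continuous",
    "teed_proxy",
    "generate_rdbs",
]

STIM_FREQUENCY_HZ = 140.1
STIM_PULSE_WIDTH_S = 60e-6


@dataclass(frozen=True)
class TherapeuticWindow:
    """Allowed amplitude range [I_min, I_max], capped at 125% clinical."""

    i_min_ma: float
    i_max_ma: float
    clinical_ma: float

    def __post_init__(self) -> None:
        if not (0 < self.i_min_ma <= self.i_max_ma):
            raise ValueError("need 0 < i_min <= i_max")
        if self.i_max_ma > 1.25 * self.clinical_ma + 1e-12:
            raise ValueError("i_max exceeds 125% of clinical amplitude")


@dataclass(frozen=True)
class RampPolicy:
    """Step size and per-direction sustained ramp rates."""

    up_ma_per_s: float = 0.1
    down_ma_per_s: float = 0.05
    step_ma: float = 0.1

    def __post_init__(self) -> None:
        if min(self.up_ma_per_s, self.down_ma_per_s, self.step_ma) <= 0:
            raise ValueError("ramp parameters must be positive")

    def min_interval_s(self, direction: int) -> float:
        rate = self.up_ma_per_s if direction > 0 else self.down_ma_per_s
        return self.step_ma / rate


@dataclass
class HemisphereConfig:
    """Per-hemisphere controller configuration."""

    side: str
    band: BandConfig
    thresholds: BurstThresholds
    window: TherapeuticWindow
    ramp: RampPolicy = field(default_factory=RampPolicy)
    mode: str = "adaptive"  # "adaptive" | "held_at_clinical"
    decision_period_s: float = 1.0
    blank_s: float = 0.5


@dataclass(frozen=True)
class Decision:
    time_s: float
    side: str
    burst_duration_s: float
    direction: int
    executed: bool
    amplitude_ma: float


@dataclass
class _HemiState:
    amplitude_ma: float
    last_step_time_s: Optional[float] = None


@dataclass
class ControllerState:
    """Mutable per-run controller state and decision log."""

    hemis: Dict[str, _HemiState]
    log: List[Decision] = field(default_factory=list)


@dataclass
class StimTrace:
    """Amplitude-vs-time record for one hemisphere (piecewise constant)."""

    series: TimeSeries
    frequency_hz: float = STIM_FREQUENCY_HZ
    pulse_width_s: float = STIM_PULSE_WIDTH_S

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def mean_ma(self) -> float:
        return float(np.mean(self.series.values)) if len(self.series) else 0.0


@dataclass
class AdaptationPattern:
    """Executed (direction, inter-step interval) pairs of an adaptive run.

    Replaying the pattern through the ramp machinery reproduces the
    source amplitude trace exactly.
    """

    initial_ma: float
    directions: np.ndarray          # +1/-1 per executed step
    intervals_s: np.ndarray         # time since previous executed step (or run start)
    window: TherapeuticWindow
    ramp: RampPolicy
    duration_s: float
    dt_s: float


def decide(current_burst_duration_s: float, duration_threshold_s: float) -> int:
    """+1 (increment) iff the burst outlasts the threshold, else -1."""
    if current_burst_duration_s < 0 or duration_threshold_s < 0:
        raise ValueError("durations must be non-negative")
    return 1 if current_burst_duration_s > duration_threshold_s else -1


def apply_step(state: ControllerState, config: HemisphereConfig, direction: int,
               now_s: float, burst_duration_s: float = float("nan")) -> bool:
    """Attempt one +/-0.1 mA step; returns True if it executed.

    A step executes only when the time since the previous executed step is
    at least step/rate for the requested direction and the result stays
    inside the therapeutic window.  Every decision is logged.
    """
    if config.mode != "adaptive":
        raise AdbsKitError("apply_step requires an adaptive hemisphere")
    hemi = state.hemis[config.side]
    ramp, window = config.ramp, config.window
    target = hemi.amplitude_ma + direction * ramp.step_ma
    ok_rate = (hemi.last_step_time_s is None or
               now_s - hemi.last_step_time_s >= ramp.min_interval_s(direction) - 1e-9)
    ok_window = window.i_min_ma - 1e-9 <= target <= window.i_max_ma + 1e-9
    executed = bool(ok_rate and ok_window)
    if executed:
        hemi.amplitude_ma = round(target, 10)
        hemi.last_step_time_s = now_s
    state.log.append(Decision(time_s=now_s, side=config.side,
                              burst_duration_s=burst_duration_s,
                              direction=direction, executed=executed,
                              amplitude_ma=hemi.amplitude_ma))
    return executed


def hold_continuous(clinical_ma: float, duration_s: float,
                    dt_s: float = 1.0) -> StimTrace:
    """Constant-amplitude (cDBS) trace at 100% clinical amplitude."""
    if clinical_ma <= 0:
        raise ValueError("clinical amplitude must be positive")
    n = int(round(duration_s / dt_s))
    return StimTrace(series=TimeSeries(values=np.full(n, clinical_ma),
                                       rate=1.0 / dt_s, units="mA"))


def teed_proxy(trace: StimTrace) -> float:
    """Unit-impedance TEED proxy: sum amplitude^2 * f * pulse_width * dt."""
    if len(trace.series) == 0:
        raise ValueError("empty stimulation trace")
    dt = 1.0 / trace.series.rate
    return float(np.sum(trace.values ** 2) * trace.frequency_hz
                 * trace.pulse_width_s * dt)


# ---------------------------------------------------------------------------
# Closed-loop runner.

class LfpSource:
    """Protocol for per-hemisphere LFP sources driven by the loop.

    ``step(amplitude_ma, n_samples) -> ndarray`` must emit the next chunk
    given the amplitude currently applied to that hemisphere.
    """

    rate: float

    def step(self, amplitude_ma: float, n_samples: int) -> np.ndarray:
        raise NotImplementedError


class RecordedSource(LfpSource):
    """Replay of a recorded LFP series (amplitude argument ignored)."""

    def __init__(self, series: TimeSeries):
        self.rate = series.rate
        self._values = series.values
        self._pos = 0

    def step(self, amplitude_ma: float, n_samples: int) -> np.ndarray:
        if self._pos + n_samples > self._values.size:
            raise AdbsKitError("recorded series shorter than the run")
        chunk = self._values[self._pos:self._pos + n_samples]
        self._pos += n_samples
        return chunk


@dataclass
class AdaptiveRunResult:
    traces: Dict[str, StimTrace]
    state: ControllerState
    bursts: Dict[str, List[BurstEvent]]
    detectors: Dict[str, BurstDetector]

    def pattern(self, side: str) -> AdaptationPattern:
        """Extract the executed-step pattern of one hemisphere."""
        steps = [(d.time_s, d.direction) for d in self.state.log
                 if d.side == side and d.executed]
        trace = self.traces[side]
        t_prev = 0.0
        dirs, ivals = [], []
        for t, direction in steps:
            dirs.append(direction)
            ivals.append(t - t_prev)
            t_prev = t
        cfg_dt = 1.0 / trace.series.rate
        return AdaptationPattern(initial_ma=float(trace.values[0]) if len(trace.series) else 0.0,
                                 directions=np.asarray(dirs, dtype=int),
                                 intervals_s=np.asarray(ivals, dtype=float),
                                 window=self._windows[side], ramp=self._ramps[side],
                                 duration_s=trace.series.duration, dt_s=cfg_dt)

    _windows: Dict[str, TherapeuticWindow] = None  # type: ignore[assignment]
    _ramps: Dict[str, RampPolicy] = None  # type: ignore[assignment]


def run_adaptive(sources: Dict[str, LfpSource],
                 configs: Sequence[HemisphereConfig],
                 duration_s: float,
                 initial_ma: Optional[Dict[str, float]] = None) -> AdaptiveRunResult:
    """Run the closed loop: sense -> burst duration -> decide -> step.

    Each hemisphere runs independently on its own LFP source, detector and
    configuration.  Adaptive hemispheres start at I_min (unless an explicit
    initial amplitude is given); held hemispheres stay at 100% clinical.
    After every executed step the detector is blanked for ``blank_s`` to
    skip the stimulation-change artifact.
    """
    configs = list(configs)
    hemis: Dict[str, _HemiState] = {}
    detectors: Dict[str, BurstDetector] = {}
    bursts: Dict[str, List[BurstEvent]] = {}
    amps: Dict[str, List[float]] = {}
    for cfg in configs:
        if cfg.mode == "adaptive":
            a0 = (initial_ma or {}).get(cfg.side, cfg.window.i_min_ma)
            if not (cfg.window.i_min_ma <= a0 <= cfg.window.i_max_ma):
                raise ValueError("initial amplitude outside therapeutic window")
        else:
            a0 = cfg.window.clinical_ma
        hemis[cfg.side] = _HemiState(amplitude_ma=a0)
        detectors[cfg.side] = BurstDetector(
            band=cfg.band, power_threshold=cfg.thresholds.power_threshold,
            rate=sources[cfg.side].rate)
        bursts[cfg.side] = []
        amps[cfg.side] = []
    state = ControllerState(hemis=hemis)

    period = configs[0].decision_period_s
    if any(c.decision_period_s != period for c in configs):
        raise ValueError("hemispheres must share a decision period")
    n_cycles = int(round(duration_s / period))
    for cyc in range(n_cycles):
        now = (cyc + 1) * period
        for cfg in configs:
            side = cfg.side
            det = detectors[side]
            n = int(round(period * sources[side].rate))
            chunk = sources[side].step(hemis[side].amplitude_ma, n)
            bursts[side].extend(det.process(chunk))
            amps[side].append(hemis[side].amplitude_ma)
            if cfg.mode != "adaptive":
                continue
            try:
                dur = det.current_burst_duration(now_s=now)
            except AdbsKitError:
                dur = 0.0
            direction = decide(dur, cfg.thresholds.duration_threshold_s)
            if apply_step(state, cfg, direction, now, burst_duration_s=dur):
                det.blank_interval(det.samples_seen / det.rate, cfg.blank_s)

    traces = {side: StimTrace(series=TimeSeries(values=np.asarray(a),
                                                rate=1.0 / period, units="mA"))
              for side, a in amps.items()}
    result = AdaptiveRunResult(traces=traces, state=state, bursts=bursts,
                               detectors=detectors)
    result._windows = {c.side: c.window for c in configs}
    result._ramps = {c.side: c.ramp for c in configs}
    return result


# ---------------------------------------------------------------------------
# Randomly adapting control condition.

def replay_pattern(pattern: AdaptationPattern) -> StimTrace:
    """Replay (direction, interval) pairs through the ramp machinery."""
    n = int(round(pattern.duration_s / pattern.dt_s))
    amp = pattern.initial_ma
    last_t: Optional[float] = None
    t = 0.0
    changes: List[Tuple[float, float]] = []
    for direction, ival in zip(pattern.directions, pattern.intervals_s):
        t += ival
        target = amp + direction * pattern.ramp.step_ma
        ok_rate = (last_t is None or
                   t - last_t >= pattern.ramp.min_interval_s(direction) - 1e-9)
        if ok_rate and (pattern.window.i_min_ma - 1e-9 <= target
                        <= pattern.window.i_max_ma + 1e-9):
            amp = round(target, 10)
            last_t = t
            changes.append((t, amp))
    values = np.full(n, pattern.initial_ma)
    for tc, a in changes:
        i = int(round(tc / pattern.dt_s))
        if i < n:
            values[i:] = a
    return StimTrace(series=TimeSeries(values=values, rate=1.0 / pattern.dt_s,
                                       units="mA"))


def generate_rdbs(pattern: AdaptationPattern, seed: int) -> StimTrace:
    """TEED-matched random adaptation (rDBS).

    The adaptation pattern of the source run — its sequence of
    constant-amplitude dwell segments — is uniformly shuffled in time.
    Each segment keeps its amplitude and dwell, so the amplitude
    distribution over the run (and therefore the TEED and the therapeutic
    window bounds) is preserved exactly while the timing of adaptation is
    decoupled from the beta biomarker.
    """
    rng = np.random.default_rng(seed)
    source = replay_pattern(pattern)
    values = source.values
    if pattern.directions.size == 0 or values.size == 0:
        return source
    change = np.flatnonzero(np.diff(values) != 0) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    segments = [values[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    order = rng.permutation(len(segments))
    shuffled = np.concatenate([segments[i] for i in order])
    return StimTrace(series=TimeSeries(values=shuffled,
                                       rate=source.series.rate, units="mA"))
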