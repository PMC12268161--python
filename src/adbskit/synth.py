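"""Ground-truth-labelled signal generators.

Four generators emulate the streams the analysis stack consumes:

* :class:`LfpPlant` — a stimulation-dependent STN LFP model: 1/f
  background, a beta oscillation gated into bursts whose mean duration
  shrinks linearly with stimulation amplitude (down to a floor), an
  elevated 45-65 Hz noise floor that anchors the trough-based power
  threshold, and an exponential artifact transient after every
  stimulation change.  It runs open-loop (fixed amplitude schedule) or
  closed-loop (chunk by chunk under the controller).
* :func:`synth_sip` — alternating force-plate loading for the
  stepping-in-place task with plantable freeze intervals (trembling or
  akinetic).
* :func:`synth_tbc` — per-stride shank angular-velocity pulses in a
  randomly rotated sensor frame, with plantable freeze segments of small
  irregular pulses.
* :func:`synth_wrist` — sinusoidal wrist flexion-extension.

Every generator is deterministic given its seed and returns the planted
truth (burst events, gait events, freeze intervals) alongside the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .burst import BandConfig
from .controller import LfpSource, StimTrace
from .gait_kinetics import ForcePlateTrial
from .gait_kinematics import ImuTrial
from .signal_io import TimeSeries

__all__ = [
    "LfpPlantParams",
    "LfpPlant",
    "SynthTruth",
    "synth_lfp",
    "GaitSynthParams",
    "synth_sip",
    "TbcSynthParams",
    "synth_tbc",
    "synth_wrist",
]


@dataclass
class SynthTruth:
    """Planted ground truth accompanying a generated signal."""

    bursts: List[Tuple[float, float]] = field(default_factory=list)   # (start, duration)
    freezes: List[Tuple[float, float]] = field(default_factory=list)  # (start, end)
    foot_off_s: Dict[str, List[float]] = field(default_factory=dict)
    foot_strike_s: Dict[str, List[float]] = field(default_factory=dict)
    swing_times_s: Dict[str, List[float]] = field(default_factory=dict)
    stride_times_s: Dict[str, List[float]] = field(default_factory=dict)
    mid_swing_s: Dict[str, List[float]] = field(default_factory=dict)
    peak_velocity_deg_s: Dict[str, List[float]] = field(default_factory=dict)
    swing_range_deg: Dict[str, List[float]] = field(default_factory=dict)
    vrms_deg_s: Optional[float] = None
    cycles_per_s: Optional[float] = None
    oscillatory: bool = True
    params: Optional[object] = None
    seed: Optional[int] = None

    @property
    def mean_burst_duration_s(self) -> float:
        return float(np.mean([d for _, d in self.bursts])) if self.bursts else float("nan")

    def freeze_fraction(self, duration_s: float) -> float:
        return sum(b - a for a, b in self.freezes) / duration_s if duration_s else 0.0


# ---------------------------------------------------------------------------
# 1/f background: cascade of first-order pole/zero sections whose average
# log-log slope equals the requested exponent.

def _pink_sos(exponent: float, rate: float, f_lo: float = 0.4,
              f_hi: float = 120.0, n_sections: int = 8) -> np.ndarray:
    f_p = np.geomspace(f_lo, f_hi, n_sections)
    step = (np.log(f_hi) - np.log(f_lo)) / (n_sections - 1)
    f_z = f_p * np.exp(step * exponent / 2.0)
    sos = []
    for fp, fz in zip(f_p, f_z):
        zp = math.exp(-2.0 * math.pi * fp / rate)
        zz = math.exp(-2.0 * math.pi * fz / rate)
        sos.append([1.0, -zz, 0.0, 1.0, -zp, 0.0])
    return np.asarray(sos)


def _band_rms_of_filtered_noise(sos: np.ndarray, rate: float,
                                lo: float, hi: float) -> float:
    """RMS within [lo, hi] Hz of unit white noise passed through ``sos``."""
    f, h = sps.sosfreqz(sos, worN=4096, fs=rate)
    psd = (2.0 / rate) * np.abs(h) ** 2
    m = (f >= lo) & (f <= hi)
    return float(np.sqrt(np.trapezoid(psd[m], f[m])))


def _total_rms(sos: np.ndarray, rate: float) -> float:
    f, h = sps.sosfreqz(sos, worN=4096, fs=rate)
    psd = (2.0 / rate) * np.abs(h) ** 2
    return float(np.sqrt(np.trapezoid(psd, f)))


@dataclass
class LfpPlantParams:
    """Stimulation-dependent LFP generator parameters.

    Burst mean duration follows ``max(d_floor_s, d0_s - k_s_per_ma * I)``
    with gamma-distributed dispersion; burst amplitude is ``snr`` times
    the broadband background RMS.  The 45-65 Hz floor
    (``gamma_noise_rms``, units of background RMS) sets where the
    trough-derived power threshold lands: above the between-burst beta
    envelope, below the burst envelope.
    """

    rate: float = 500.0
    one_over_f_exponent: float = 1.0
    background_rms: float = 1.0
    beta_center_hz: float = 15.0
    band_width_hz: float = 6.0
    burst_rate_hz: float = 0.8          # hazard of a new burst when idle
    d0_s: float = 0.5                   # mean duration at 0 mA
    k_s_per_ma: float = 0.075           # shortening per mA
    d_floor_s: float = 0.1
    gamma_shape: float = 4.0
    snr: float = 3.0
    gamma_noise_rms: float = 2.1
    edge_s: float = 0.05                # raised-cosine burst edges
    artifact_peak_factor: float = 10.0  # x burst amplitude
    artifact_tau_s: float = 0.1
    # During a burst the in-band background is cross-faded into the
    # oscillation (a burst is transient synchronization of the same
    # population, not an added independent source).
    suppress_band_in_burst: bool = True

    def duration_law(self, amplitude_ma: float) -> float:
        return max(self.d_floor_s, self.d0_s - self.k_s_per_ma * amplitude_ma)


class LfpPlant(LfpSource):
    """Streaming LFP plant; emits chunks at the currently applied amplitude."""

    def __init__(self, params: LfpPlantParams, seed: int):
        p = params
        self.params = p
        self.seed = seed
        self.rate = p.rate
        # independent streams so output is invariant to chunking
        self._rng_pink = np.random.default_rng([seed, 1])
        self._rng_gamma = np.random.default_rng([seed, 2])
        self._rng = np.random.default_rng([seed, 3])   # burst schedule
        self._pink = _pink_sos(p.one_over_f_exponent, p.rate)
        self._pink_zi = np.zeros((self._pink.shape[0], 2))
        self._pink_gain = p.background_rms / _total_rms(self._pink, p.rate)
        lo = p.beta_center_hz - p.band_width_hz / 2.0
        hi = p.beta_center_hz + p.band_width_hz / 2.0
        self.burst_amplitude = p.snr * p.background_rms
        # linear-phase FIR isolating the in-band background, plus a
        # matched delay of the wideband path so the two stay aligned
        from .signal_io import design_fir_bandpass

        self._band_b = design_fir_bandpass((lo + hi) / 2.0, hi - lo, 128, p.rate).b
        self._band_zi = np.zeros(self._band_b.size - 1)
        self._delay = self._band_b.size // 2
        self._delay_buf = np.zeros(self._delay)
        self._gsos = sps.butter(4, [45.0, 65.0], btype="band", fs=p.rate, output="sos")
        self._gzi = np.zeros((self._gsos.shape[0], 2))
        graw = _band_rms_of_filtered_noise(self._gsos, p.rate, 0.0, p.rate / 2.0)
        self._ggain = p.gamma_noise_rms * p.background_rms / graw
        self._n = 0                       # samples emitted
        self._next_start: float = float(self._rng.exponential(1.0 / p.burst_rate_hz))
        self._burst_end: float = -1.0     # end (incl. trailing edge) of active burst
        self._active: Optional[Tuple[float, float]] = None  # (start, duration)
        self._last_amp: Optional[float] = None
        self._artifacts: List[float] = []  # start times of pending transients
        self._events: List[Tuple[float, float]] = []
        self.truth = SynthTruth(params=p, seed=seed)

    # -- internal: make sure burst schedule covers [t0, t1)
    def _schedule_until(self, t1: float, amplitude_ma: float) -> None:
        p = self.params
        while self._next_start < t1:
            start = self._next_start
            mean = p.duration_law(amplitude_ma)
            dur = float(self._rng.gamma(p.gamma_shape, mean / p.gamma_shape))
            dur = max(dur, 2 * p.edge_s)
            self.truth.bursts.append((start, dur))
            self._events.append((start, dur))
            self._next_start = start + dur + p.edge_s + float(
                self._rng.exponential(1.0 / p.burst_rate_hz))

    def step(self, amplitude_ma: float, n_samples: int) -> np.ndarray:
        p = self.params
        t0 = self._n / p.rate
        t1 = (self._n + n_samples) / p.rate
        t = t0 + np.arange(n_samples) / p.rate
        self._schedule_until(t1, amplitude_ma)

        white = self._rng_pink.standard_normal(n_samples)
        pink, self._pink_zi = sps.sosfilt(self._pink, white, zi=self._pink_zi)
        pink = pink * self._pink_gain
        gwhite = self._rng_gamma.standard_normal(n_samples)
        gnoise, self._gzi = sps.sosfilt(self._gsos, gwhite, zi=self._gzi)

        gate = np.zeros(n_samples)
        keep: List[Tuple[float, float]] = []
        for start, dur in self._events:
            lo = start - p.edge_s / 2.0
            hi = start + dur + p.edge_s / 2.0
            if hi < t0:
                continue
            keep.append((start, dur))
            if lo >= t1:
                continue
            m = (t >= lo) & (t < hi)
            u = t[m] - lo
            g = np.ones(u.size)
            rise = u < p.edge_s
            g[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / p.edge_s))
            fall = u > (hi - lo) - p.edge_s
            g[fall] = 0.5 * (1.0 - np.cos(np.pi * ((hi - lo) - u[fall]) / p.edge_s))
            gate[m] = np.maximum(gate[m], g)
        self._events = keep

        if p.suppress_band_in_burst:
            band, self._band_zi = sps.lfilter(self._band_b, [1.0], pink,
                                              zi=self._band_zi)
            joined = np.concatenate([self._delay_buf, pink])
            delayed = joined[:n_samples]
            self._delay_buf = joined[n_samples:]
            out = delayed - gate * band
        else:
            out = pink
        out = out + gnoise * self._ggain
        out = out + self.burst_amplitude * gate * np.sin(
            2.0 * np.pi * p.beta_center_hz * t)

        if self._last_amp is not None and amplitude_ma != self._last_amp:
            self._artifacts.append(t0)
        self._last_amp = amplitude_ma
        live: List[float] = []
        peak = p.artifact_peak_factor * self.burst_amplitude
        for ta in self._artifacts:
            if t0 - ta < 6.0 * p.artifact_tau_s:
                live.append(ta)
                m = t >= ta
                out[m] = out[m] + peak * np.exp(-(t[m] - ta) / p.artifact_tau_s)
        self._artifacts = live

        self._n += n_samples
        return out

    @property
    def band(self) -> BandConfig:
        return BandConfig(center_hz=self.params.beta_center_hz,
                          width_hz=self.params.band_width_hz)


def synth_lfp(params: LfpPlantParams, stim: StimTrace | float, duration_s: float,
              seed: int, chunk_s: float = 1.0) -> Tuple[TimeSeries, SynthTruth]:
    """Open-loop LFP under a fixed amplitude or a recorded amplitude trace."""
    plant = LfpPlant(params, seed)
    n_chunk = int(round(chunk_s * params.rate))
    n_total = int(round(duration_s * params.rate))
    chunks = []
    emitted = 0
    while emitted < n_total:
        n = min(n_chunk, n_total - emitted)
        t = emitted / params.rate
        if isinstance(stim, StimTrace):
            i = min(int(t * stim.series.rate), len(stim.series) - 1)
            amp = float(stim.values[i]) if len(stim.series) else 0.0
        else:
            amp = float(stim)
        chunks.append(plant.step(amp, n))
        emitted += n
    values = np.concatenate(chunks) if chunks else np.empty(0)
    sig = TimeSeries(values=values, rate=params.rate, units="uV", label="lfp")
    plant.truth.bursts = [(s, d) for s, d in plant.truth.bursts
                          if s + d <= duration_s]
    return sig, plant.truth


# ---------------------------------------------------------------------------
# Stepping-in-place force plates.

@dataclass
class GaitSynthParams:
    """Stepping-in-place generator parameters.

    ``asymmetry_factor`` is the left/right swing-time ratio; planted swing
    times are defined at the 20% body-weight crossing level.  Freezes
    replace stepping with 5 Hz trembling between 30 and 70% body weight
    (style "trembling") or a static 50/50 split ("akinetic").
    """

    duration_s: float = 100.0
    rate: float = 1000.0
    cadence_hz: float = 1.0             # strides per second
    swing_s: float = 0.3                # right-leg swing time
    asymmetry_factor: float = 1.0       # left swing = factor * right swing
    stride_time_cv: float = 0.03
    freeze_intervals: Optional[Sequence[Tuple[float, float]]] = None
    freeze_fraction: float = 0.0
    freeze_style: str = "trembling"     # "trembling" | "akinetic"
    trembling_hz: float = 5.0
    transition_s: float = 0.06
    body_weight_n: float = 700.0

    def resolved_freezes(self) -> List[Tuple[float, float]]:
        if self.freeze_intervals is not None:
            iv = sorted((float(a), float(b)) for a, b in self.freeze_intervals)
            for (a0, b0), (a1, _) in zip(iv, iv[1:]):
                if a1 < b0:
                    raise ValueError("freeze intervals overlap")
            return iv
        if self.freeze_fraction > 0:
            span = self.freeze_fraction * self.duration_s
            mid = self.duration_s / 2.0
            return [(mid - span / 2.0, mid + span / 2.0)]
        return []


def _raised_cosine(n: int, a: float, b: float) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    return b + (a - b) * 0.5 * (1.0 + np.cos(np.pi * u))


def synth_sip(params: GaitSynthParams, seed: int) -> Tuple[ForcePlateTrial, SynthTruth]:
    """Alternating load transfer between two plates with plantable freezes.

    The left-load fraction w(t) cycles 0.5 -> 0 (left swing) -> 0.5 -> 1
    (right swing) -> 0.5 with raised-cosine transitions, timed so the time
    each leg spends below the 20% crossing equals its planted swing time.
    """
    p = params
    rng = np.random.default_rng(seed)
    rate = p.rate
    n_total = int(round(p.duration_s * rate))
    w = np.full(n_total, 0.5)
    truth = SynthTruth(params=p, seed=seed,
                       foot_off_s={"left": [], "right": []},
                       foot_strike_s={"left": [], "right": []},
                       swing_times_s={"left": [], "right": []},
                       stride_times_s={"left": [], "right": []})
    freezes = p.resolved_freezes()
    tau = p.transition_s
    # time from the start of a 0.5->0 transition to the 20% crossing
    u_star = tau * math.acos(4 * 0.2 - 1.0) / math.pi
    edge_over = 2.0 * (tau - u_star)   # crossing-level time added by the edges
    T = 1.0 / p.cadence_hz
    swings = {"left": p.asymmetry_factor * p.swing_s, "right": p.swing_s}
    last_strike = {"left": None, "right": None}

    def fill(i0: int, i1: int, arr: np.ndarray) -> None:
        seg = arr[: max(0, min(i1, n_total) - i0)]
        if seg.size:
            w[i0:i0 + seg.size] = seg

    t = 0.0
    fz = list(freezes)
    while t < p.duration_s - 1e-9:
        if fz and t >= fz[0][0] - T / 2.0:
            a, b = fz.pop(0)
            start, end = t, min(t + (b - a), p.duration_s)
            i0, i1 = int(round(start * rate)), int(round(end * rate))
            tt = np.arange(i0, min(i1, n_total)) / rate
            if p.freeze_style == "trembling":
                w[i0:i0 + tt.size] = 0.5 + 0.2 * np.sin(
                    2.0 * np.pi * p.trembling_hz * (tt - start))
            else:
                w[i0:i0 + tt.size] = 0.5
            truth.freezes.append((start, end))
            last_strike = {"left": None, "right": None}
            t = end
            continue
        period = T * (1.0 + p.stride_time_cv * float(rng.standard_normal()))
        # one cycle: left swing then right swing, dwells fill the rest
        cyc = []
        for leg, level in (("left", 0.0), ("right", 1.0)):
            hold = swings[leg] - edge_over
            if hold <= 0:
                raise ValueError("swing time too short for the transition length")
            cyc.append((leg, level, hold))
        used = sum(h + 2 * tau for _, _, h in cyc)
        dwell = max(0.02, (period - used) / 2.0)
        tc = t
        for leg, level, hold in cyc:
            n_tau = int(round(tau * rate))
            i = int(round(tc * rate))
            fill(i, i + n_tau, _raised_cosine(n_tau, 0.5, level))
            i2 = i + n_tau
            n_hold = int(round(hold * rate))
            if i2 < n_total:
                w[i2:min(i2 + n_hold, n_total)] = level
            i3 = i2 + n_hold
            fill(i3, i3 + n_tau, _raised_cosine(n_tau, level, 0.5))
            off_t = tc + u_star
            strike_t = tc + tau + hold + (tau - u_star)
            if strike_t < p.duration_s:
                truth.foot_off_s[leg].append(off_t)
                truth.foot_strike_s[leg].append(strike_t)
                truth.swing_times_s[leg].append(strike_t - off_t)
                if last_strike[leg] is not None:
                    truth.stride_times_s[leg].append(strike_t - last_strike[leg])
                last_strike[leg] = strike_t
            tc += 2 * tau + hold + dwell
        t += period
    bw = p.body_weight_n
    left = TimeSeries(values=bw * w, rate=rate, units="N", label="left")
    right = TimeSeries(values=bw * (1.0 - w), rate=rate, units="N", label="right")
    return ForcePlateTrial(left=left, right=right, body_weight_n=bw), truth


# ---------------------------------------------------------------------------
# Turning-and-barrier-course shank IMU.

@dataclass
class TbcSynthParams:
    """Shank angular-velocity generator parameters.

    Normal strides are sin^2 velocity pulses of the planted peak and swing
    duration on a small negative baseline (stance counter-rotation);
    freezes are runs of small, short, irregular pulses.
    """

    duration_s: float = 120.0
    rate: float = 128.0
    stride_period_s: float = 1.1
    swing_s: float = 0.4
    peak_deg_s: float = 300.0
    baseline_deg_s: Optional[float] = None   # None: balance so the mean is ~0
    stride_time_cv: float = 0.03
    asymmetry_factor: float = 1.0       # left swing = factor * right swing
    noise_deg_s: float = 4.0
    freeze_intervals: Optional[Sequence[Tuple[float, float]]] = None
    freeze_fraction: float = 0.0
    freeze_peak_deg_s: float = 150.0    # small rapid shuffling steps
    freeze_period_s: float = 0.55
    freeze_period_cv: float = 0.35
    freeze_swing_s: float = 0.22

    def resolved_freezes(self) -> List[Tuple[float, float]]:
        if self.freeze_intervals is not None:
            return sorted((float(a), float(b)) for a, b in self.freeze_intervals)
        if self.freeze_fraction > 0:
            span = self.freeze_fraction * self.duration_s
            mid = self.duration_s / 2.0
            return [(mid - span / 2.0, mid + span / 2.0)]
        return []

    def resolved_baseline(self) -> float:
        """Stance counter-rotation balancing the swing pulse (zero-mean
        shank rotation over a stride)."""
        if self.baseline_deg_s is not None:
            return self.baseline_deg_s
        return (self.peak_deg_s * self.swing_s / 2.0) / (
            self.stride_period_s - self.swing_s / 2.0)


def _pulse_truth(peak: float, base: float, swing: float, rate: float
                 ) -> Tuple[float, float]:
    """(swing range, actual peak) of one pulse between its zero crossings."""
    tt = np.arange(0.0, swing, 1.0 / rate)
    v = -base + (peak + base) * np.sin(np.pi * tt / swing) ** 2
    pos = v > 0
    if not pos.any():
        return 0.0, 0.0
    i0, i1 = np.flatnonzero(pos)[[0, -1]]
    return float(np.trapezoid(v[i0:i1 + 1], dx=1.0 / rate)), float(v.max())


def synth_tbc(params: TbcSynthParams, seed: int) -> Tuple[ImuTrial, SynthTruth]:
    p = params
    rng = np.random.default_rng(seed)
    rate = p.rate
    n_total = int(round(p.duration_s * rate))
    truth = SynthTruth(params=p, seed=seed,
                       mid_swing_s={"left": [], "right": []},
                       stride_times_s={"left": [], "right": []},
                       swing_times_s={"left": [], "right": []},
                       peak_velocity_deg_s={"left": [], "right": []},
                       swing_range_deg={"left": [], "right": []})
    base = p.resolved_baseline()
    sag = {"left": np.full(n_total, -base),
           "right": np.full(n_total, -base)}
    freezes = p.resolved_freezes()
    truth.freezes = [(a, min(b, p.duration_s)) for a, b in freezes]

    def in_freeze(t: float) -> bool:
        return any(a <= t < b for a, b in freezes)

    def add_pulse(leg: str, t0: float, peak: float, swing: float) -> None:
        i0 = int(round(t0 * rate))
        nn = int(round(swing * rate))
        if i0 >= n_total or nn < 2:
            return
        tt = np.arange(nn) / rate
        v = -base + (peak + base) * np.sin(np.pi * tt / swing) ** 2
        seg = v[: max(0, min(i0 + nn, n_total) - i0)]
        sag[leg][i0:i0 + seg.size] = seg

    last_mid = {"left": None, "right": None}
    for leg, phase in (("left", 0.0), ("right", 0.5)):
        swing = p.swing_s * (p.asymmetry_factor if leg == "left" else 1.0)
        t = phase * p.stride_period_s
        while t < p.duration_s - swing:
            if in_freeze(t):
                period = p.freeze_period_s * (
                    1.0 + p.freeze_period_cv * float(rng.standard_normal()))
                period = max(0.25, period)
                pk = p.freeze_peak_deg_s * float(rng.uniform(0.6, 1.4))
                add_pulse(leg, t, pk, p.freeze_swing_s)
                t += period
                continue
            period = p.stride_period_s * (
                1.0 + p.stride_time_cv * float(rng.standard_normal()))
            add_pulse(leg, t, p.peak_deg_s, swing)
            mid = t + swing / 2.0
            rng_deg, pk = _pulse_truth(p.peak_deg_s, base, swing, rate)
            truth.mid_swing_s[leg].append(mid)
            truth.swing_times_s[leg].append(swing)
            truth.peak_velocity_deg_s[leg].append(pk)
            truth.swing_range_deg[leg].append(rng_deg)
            prev = last_mid[leg]
            if prev is not None and not any(a < mid and b > prev
                                            for a, b in freezes):
                truth.stride_times_s[leg].append(mid - prev)
            last_mid[leg] = mid
            t += period

    sensors: Dict[str, np.ndarray] = {}
    for leg in ("left", "right"):
        # random sensor orientation: sagittal axis is an arbitrary unit vector
        q = rng.standard_normal((3, 3))
        rot, _ = np.linalg.qr(q)
        axis = rot[:, 0]
        xyz = np.outer(sag[leg], axis)
        xyz += p.noise_deg_s * rng.standard_normal(xyz.shape)
        sensors[f"{leg}_shank"] = xyz
    return ImuTrial(sensors=sensors, rate=rate), truth


# ---------------------------------------------------------------------------
# Wrist flexion-extension.

def synth_wrist(freq_hz: float = 1.5, amplitude_deg_s: float = 100.0,
                noise_deg_s: float = 0.0, duration_s: float = 30.0,
                seed: int = 0, rate: float = 128.0
                ) -> Tuple[TimeSeries, SynthTruth]:
    """Sinusoidal flexion-extension angular velocity plus sensor noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * rate))) / rate
    v = amplitude_deg_s * np.sin(2.0 * np.pi * freq_hz * t)
    if noise_deg_s > 0:
        v = v + noise_deg_s * rng.standard_normal(t.size)
    truth = SynthTruth(vrms_deg_s=amplitude_deg_s / math.sqrt(2.0),
                       cycles_per_s=freq_hz,
                       oscillatory=amplitude_deg_s > 0,
                       seed=seed)
    return TimeSeries(values=v, rate=rate, units="deg/s", label="hand"), truth
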