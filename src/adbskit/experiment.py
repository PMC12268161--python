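"""End-to-end in-silico experiment: calibrate, run the four stimulation
conditions on the same generators, and compare behavioural metrics.

Conditions: OFF, continuous stimulation at the clinical amplitude (cDBS),
burst-duration adaptive stimulation (aDBS), and the TEED-matched randomly
adapting control (rDBS) built by shuffling the aDBS adaptation pattern.

The neural-to-behavioural linkage is an explicit simulation device, not
an empirical claim: the mean burst duration implied by a condition's
amplitude trace (through the plant's duration law) sets the freeze
fraction, stride-time variability, swing asymmetry and movement vigour of
the behavioural generators via logistic maps.  With the linkage gain at
zero all conditions produce statistically indistinguishable behaviour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from . import burst as bd
from . import calibration as cal
from . import gait_kinematics as gk
from . import gait_kinetics as gf
from .burst import BandConfig, BurstThresholds
from .controller import (
    HemisphereConfig,
    StimTrace,
    TherapeuticWindow,
    generate_rdbs,
    hold_continuous,
    run_adaptive,
    teed_proxy,
)
from .errors import AdbsKitError, UndefinedMetricError
from .signal_io import TimeSeries
from .synth import (
    GaitSynthParams,
    LfpPlant,
    LfpPlantParams,
    TbcSynthParams,
    synth_lfp,
    synth_sip,
    synth_tbc,
    synth_wrist,
)

CONDITIONS = ("OFF", "cDBS", "aDBS", "rDBS")


@dataclass
class Linkage:
    """Logistic maps from mean burst duration (s) to behaviour parameters."""

    gain_per_s: float = 25.0
    midpoint_s: float = 0.4
    freeze_fraction_max: float = 0.6
    stride_cv_range: Tuple[float, float] = (0.03, 0.12)
    asymmetry_factor_range: Tuple[float, float] = (1.0, 0.75)
    wrist_amplitude_range: Tuple[float, float] = (140.0, 60.0)
    wrist_freq_range: Tuple[float, float] = (2.0, 1.2)
    shank_peak_range: Tuple[float, float] = (320.0, 180.0)

    def _mix(self, rng: Tuple[float, float], dur_s: float) -> float:
        z = expit(self.gain_per_s * (dur_s - self.midpoint_s))
        return rng[0] + (rng[1] - rng[0]) * z

    def freeze_fraction(self, dur_s: float) -> float:
        return self.freeze_fraction_max * expit(
            self.gain_per_s * (dur_s - self.midpoint_s)) if self.gain_per_s else 0.0

    def gait_params(self, dur_s: float, duration_s: float = 100.0) -> GaitSynthParams:
        g = self.gain_per_s
        return GaitSynthParams(
            duration_s=duration_s,
            stride_time_cv=self._mix(self.stride_cv_range, dur_s) if g else 0.03,
            asymmetry_factor=self._mix(self.asymmetry_factor_range, dur_s) if g else 1.0,
            freeze_fraction=self.freeze_fraction(dur_s))

    def tbc_params(self, dur_s: float, duration_s: float = 120.0) -> TbcSynthParams:
        g = self.gain_per_s
        return TbcSynthParams(
            duration_s=duration_s,
            stride_time_cv=self._mix(self.stride_cv_range, dur_s) if g else 0.03,
            asymmetry_factor=self._mix(self.asymmetry_factor_range, dur_s) if g else 1.0,
            peak_deg_s=self._mix(self.shank_peak_range, dur_s) if g else 300.0,
            freeze_fraction=self.freeze_fraction(dur_s))

    def wrist_params(self, dur_s: float) -> Tuple[float, float]:
        if not self.gain_per_s:
            return 1.5, 100.0
        return (self._mix(self.wrist_freq_range, dur_s),
                self._mix(self.wrist_amplitude_range, dur_s))


def build_freeze_corpus(n_trials: int = 12, seed: int = 0,
                        freeze_fraction: float = 0.35,
                        duration_s: float = 120.0
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Labelled per-step feature corpus for fitting the freeze model.

    Trials alternate between freeze-free walking and walking with a
    planted freeze segment; each detected step is labelled by whether its
    mid-swing falls inside a planted freeze interval.
    """
    rng = np.random.default_rng(seed)
    X: List[np.ndarray] = []
    y: List[int] = []
    for k in range(n_trials):
        frac = freeze_fraction if k % 2 else 0.0
        params = TbcSynthParams(duration_s=duration_s, freeze_fraction=frac)
        imu, truth = synth_tbc(params, seed=int(rng.integers(2 ** 31)))
        tables = []
        for name in ("left_shank", "right_shank"):
            sag, _ = gk.extract_sagittal(imu.sensors[name], rate=imu.rate)
            tables.append(gk.segment_strides_imu(sag, leg=name.split("_")[0]))
        steps, feats = gk.step_features(tables)
        for step, row in zip(steps, feats):
            if not np.all(np.isfinite(row)):
                continue
            frozen = any(a <= step.mid_swing_s < b for a, b in truth.freezes)
            X.append(row)
            y.append(int(frozen))
    return np.asarray(X), np.asarray(y)


def default_freeze_model(seed: int = 0) -> gk.FreezeModel:
    """Freeze model fitted on the packaged synthetic corpus."""
    X, y = build_freeze_corpus(seed=seed)
    return gk.fit_freeze_model(X, y, seed=seed)


@dataclass
class ExperimentConfig:
    plant: LfpPlantParams = field(default_factory=LfpPlantParams)
    clinical_ma: float = 3.0
    window: Optional[TherapeuticWindow] = None
    thresholds: Optional[BurstThresholds] = None
    band: Optional[BandConfig] = None
    linkage: Linkage = field(default_factory=Linkage)
    run_duration_s: float = 300.0
    sip_duration_s: float = 100.0
    tbc_duration_s: float = 120.0
    decision_period_s: float = 1.0


@dataclass
class ConditionResult:
    condition: str
    seed: int
    mean_amplitude_ma: float
    teed: float
    mean_burst_duration_s: float      # implied by the plant's duration law
    detected_burst_duration_s: Optional[float]
    percent_time_freezing: Optional[float]
    asymmetry: Optional[float]
    arrhythmicity: Optional[float]
    mean_peak_shank_angular_velocity: Optional[float]
    vrms: Optional[float]
    cycles_per_second: Optional[float]

    def metrics(self) -> Dict[str, Optional[float]]:
        d = dataclasses.asdict(self)
        for k in ("condition", "seed"):
            d.pop(k)
        return d


def calibrate_from_titrations(plant_params: LfpPlantParams, clinical_ma: float,
                              linkage: Linkage, seed: int,
                              level_duration_s: float = 60.0,
                              levels_pct: Sequence[float] = (0, 25, 50, 75, 100, 125),
                              ) -> cal.CalibrationResult:
    """Run synthetic titrations and calibrate band/thresholds/window."""
    runs: List[cal.TitrationRun] = []
    for i, pct in enumerate(levels_pct):
        amp = clinical_ma * pct / 100.0
        lfp, truth = synth_lfp(plant_params, amp, level_duration_s,
                               seed=seed * 1009 + i)
        dur = plant_params.duration_law(amp)
        behavior = 100.0 * linkage.freeze_fraction(dur) / max(
            linkage.freeze_fraction_max, 1e-9)
        runs.append(cal.TitrationRun(amplitude_ma=amp, amplitude_pct=pct,
                                     lfp=lfp, behavior=behavior))
    return cal.calibrate_hemisphere(runs, clinical_ma)


def _implied_duration(plant_params: LfpPlantParams, trace: StimTrace) -> float:
    vals = trace.values if len(trace.series) else np.zeros(1)
    return float(np.mean([plant_params.duration_law(a) for a in vals]))


def _detected_duration(plant_params: LfpPlantParams, trace: StimTrace,
                       band: BandConfig, power_threshold: float,
                       seed: int) -> Optional[float]:
    duration = trace.series.duration if len(trace.series) else 0.0
    if duration < 10:
        return None
    lfp, _ = synth_lfp(plant_params, trace, duration, seed=seed)
    env = bd.compute_envelope(lfp, band)
    events = [e for e in bd.extract_bursts(env, power_threshold) if not e.ongoing]
    if not events:
        return None
    return float(np.mean([e.duration_s for e in events]))


def run_condition(condition: str, config: ExperimentConfig, seed: int,
                  freeze_model: Optional[gk.FreezeModel] = None,
                  adbs_pattern_cache: Optional[dict] = None) -> ConditionResult:
    """Simulate one condition for one seed and compute all metrics."""
    p = config.plant
    band = config.band or BandConfig(p.beta_center_hz, p.band_width_hz)
    window = config.window
    thresholds = config.thresholds
    if window is None or thresholds is None:
        raise AdbsKitError("calibration (window + thresholds) required")
    dt = config.decision_period_s
    n = int(round(config.run_duration_s / dt))

    if condition == "OFF":
        trace = StimTrace(series=TimeSeries(values=np.zeros(n), rate=1.0 / dt,
                                            units="mA"))
        teed = 0.0
    elif condition == "cDBS":
        trace = hold_continuous(config.clinical_ma, config.run_duration_s, dt_s=dt)
        teed = teed_proxy(trace)
    else:
        cache_key = seed
        cached = (adbs_pattern_cache or {}).get(cache_key)
        if cached is None:
            cfg = HemisphereConfig(side="L", band=band, thresholds=thresholds,
                                   window=window, decision_period_s=dt)
            plant = LfpPlant(p, seed=seed * 7919 + 1)
            res = run_adaptive({"L": plant}, [cfg], config.run_duration_s)
            cached = (res.traces["L"], res.pattern("L"))
            if adbs_pattern_cache is not None:
                adbs_pattern_cache[cache_key] = cached
        adbs_trace, pattern = cached
        trace = adbs_trace if condition == "aDBS" else generate_rdbs(
            pattern, seed=seed * 7919 + 2)
        teed = teed_proxy(trace)

    cond_ix = CONDITIONS.index(condition)
    sub = seed * 7919 + 101 * cond_ix
    dur = _implied_duration(p, trace)
    detected = _detected_duration(p, trace, band, thresholds.power_threshold,
                                  seed=sub + 3)

    # behavioural tasks under the linkage
    gait = config.linkage.gait_params(dur, config.sip_duration_s)
    trial, _ = synth_sip(gait, seed=sub + 4)
    lpct, rpct = gf.normalize_to_bodyweight(trial)
    fz = gf.detect_freezes_forceplate(lpct, rpct)
    pct_freeze = gf.percent_time_freezing(fz)
    table = gf.segment_cycles_force(lpct, rpct)
    try:
        asym = gf.asymmetry(table.left.swing_times_s, table.right.swing_times_s)
        arr = gf.arrhythmicity(table.left.stride_times_s, table.right.stride_times_s)
    except UndefinedMetricError:
        asym = arr = None

    tbc = config.linkage.tbc_params(dur, config.tbc_duration_s)
    imu, _ = synth_tbc(tbc, seed=sub + 5)
    tables = []
    for name in ("left_shank", "right_shank"):
        sag, _ = gk.extract_sagittal(imu.sensors[name], rate=imu.rate)
        tables.append(gk.segment_strides_imu(sag, leg=name.split("_")[0]))
    try:
        peak = gk.mean_peak_shank_angular_velocity(tables)
    except UndefinedMetricError:
        peak = None

    wf, wa = config.linkage.wrist_params(dur)
    hand, _ = synth_wrist(freq_hz=wf, amplitude_deg_s=wa, noise_deg_s=3.0,
                          seed=sub + 6)
    vrms = gk.wrist_vrms(hand)
    cps = gk.wrist_cycles_per_second(hand)

    return ConditionResult(
        condition=condition, seed=seed,
        mean_amplitude_ma=trace.mean_ma, teed=teed,
        mean_burst_duration_s=dur, detected_burst_duration_s=detected,
        percent_time_freezing=pct_freeze, asymmetry=asym, arrhythmicity=arr,
        mean_peak_shank_angular_velocity=peak, vrms=vrms, cycles_per_second=cps)


def run_experiment(config: ExperimentConfig, seeds: Sequence[int],
                   conditions: Sequence[str] = CONDITIONS,
                   randomize_order: bool = True) -> Dict:
    """Run every condition for every seed; return a machine-readable report."""
    if config.window is None or config.thresholds is None:
        raise AdbsKitError("run_experiment needs a calibrated config")
    results: List[ConditionResult] = []
    cache: dict = {}
    for seed in seeds:
        order = list(conditions)
        if randomize_order:
            np.random.default_rng(seed).shuffle(order)
        for cond in order:
            results.append(run_condition(cond, config, seed,
                                         adbs_pattern_cache=cache))
    report: Dict = {"seeds": list(seeds), "conditions": list(conditions),
                    "per_condition": {}, "results": []}
    metric_names = ["mean_amplitude_ma", "teed", "mean_burst_duration_s",
                    "percent_time_freezing", "asymmetry", "arrhythmicity",
                    "mean_peak_shank_angular_velocity", "vrms",
                    "cycles_per_second"]
    for r in results:
        report["results"].append({"condition": r.condition, "seed": r.seed,
                                  **{k: v for k, v in r.metrics().items()}})
    for cond in conditions:
        sub = [r for r in results if r.condition == cond]
        stats = {}
        for m in metric_names:
            vals = [getattr(r, m) for r in sub if getattr(r, m) is not None]
            stats[m] = {"mean": float(np.mean(vals)) if vals else None,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                        "n": len(vals)}
        report["per_condition"][cond] = stats
    return report
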