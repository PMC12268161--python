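"""Titration spectra, band selection, thresholds and therapeutic window."""

import numpy as np
import pytest

from adbskit import calibration as cal
from adbskit.burst import BandConfig
from adbskit.errors import InsufficientDataError, NoPeakError, NoWindowError
from adbskit.signal_io import TimeSeries, welch_psd
from adbskit.synth import LfpPlantParams, synth_lfp

CLINICAL = 3.0


def _titration_runs(plant=None, seed=0, levels=(0, 25, 50, 75, 100, 125),
                    behavior=None, duration=40.0):
    plant = plant or LfpPlantParams()
    runs = []
    for i, pct in enumerate(levels):
        amp = CLINICAL * pct / 100.0
        lfp, _ = synth_lfp(plant, amp, duration, seed=seed * 977 + i)
        beh = behavior[i] if behavior is not None else None
        runs.append(cal.TitrationRun(amplitude_ma=amp, amplitude_pct=pct,
                                     lfp=lfp, behavior=beh))
    return runs


@pytest.fixture(scope="module")
def runs():
    return _titration_runs(seed=1)


@pytest.fixture(scope="module")
def power_thr(runs):
    from adbskit.burst import power_threshold_from_gamma

    return power_threshold_from_gamma(runs[0].lfp)


class TestTitrationSpectra:
    def test_beta_band_power_decreases_with_stimulation(self, runs):
        psds = cal.titration_spectra(runs)
        powers = [p.band_power(13.0, 30.0) for p in psds]
        # monotone trend: top level well below OFF
        assert powers[-1] < 0.6 * powers[0]
        assert np.corrcoef(np.arange(len(powers)), powers)[0, 1] < 0

    def test_single_run_rejected(self, runs):
        with pytest.raises(InsufficientDataError):
            cal.titration_spectra(runs[:1])


class TestBetaPeaks:
    def test_planted_peak_found(self, runs):
        peaks = cal.find_beta_peaks(welch_psd(runs[0].lfp))
        assert any(abs(p - 15.0) <= 1.0 for p in peaks)

    def test_flat_one_over_f_spectrum_has_no_peak(self, rng):
        p = LfpPlantParams(burst_rate_hz=1e-6, snr=0.0)
        lfp, _ = synth_lfp(p, 0.0, 40.0, seed=3)
        with pytest.raises(NoPeakError):
            cal.find_beta_peaks(welch_psd(lfp))

    def test_modulated_peak_preferred_over_unmodulated(self, power_thr):
        # two rhythms: 15 Hz modulated by stimulation, 25 Hz constant
        base = LfpPlantParams()
        runs = []
        for i, pct in enumerate((0, 25, 50, 75, 100, 125)):
            amp = CLINICAL * pct / 100.0
            lfp, _ = synth_lfp(base, amp, 40.0, seed=900 + i)
            t = lfp.times()
            fixed = 1.5 * np.sin(2 * np.pi * 25.0 * t)
            lfp = TimeSeries(values=lfp.values + fixed, rate=lfp.rate)
            runs.append(cal.TitrationRun(amplitude_ma=amp, amplitude_pct=pct,
                                         lfp=lfp))
        band, slope = cal.select_beta_band(runs, power_thr)
        assert abs(band.center_hz - 15.0) <= 1.0
        assert slope < 0

    def test_band_selection_invariant_to_gain(self, runs, power_thr):
        band1, _ = cal.select_beta_band(runs, power_thr)
        scaled = [
            cal.TitrationRun(amplitude_ma=r.amplitude_ma,
                             amplitude_pct=r.amplitude_pct,
                             lfp=TimeSeries(values=5.0 * r.lfp.values,
                                            rate=r.lfp.rate))
            for r in runs
        ]
        band2, _ = cal.select_beta_band(scaled, 25.0 * power_thr)
        assert band2.center_hz == band1.center_hz


class TestDurationThreshold:
    def test_constant_planted_durations_recovered_exactly(self):
        # constructed envelope-style signal: bursts of exactly 0.3 s
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        gate = ((t % 2.0) < 0.3).astype(float)
        lfp = TimeSeries(values=3.0 * gate * np.sin(2 * np.pi * 15 * t)
                         + 0.01 * np.sin(2 * np.pi * 55 * t), rate=fs)
        run = cal.TitrationRun(amplitude_ma=0.0, amplitude_pct=0.0, lfp=lfp)
        # threshold mid-rise of the FIR-smoothed burst envelope
        thr = cal.initial_duration_threshold(run, BandConfig(15.0), 2.0)
        assert thr == pytest.approx(0.3, abs=0.03)

    def test_gamma_distributed_durations_recovered(self, power_thr):
        p = LfpPlantParams(d0_s=0.4)
        lfp, truth = synth_lfp(p, 0.0, 120.0, seed=21)
        run = cal.TitrationRun(amplitude_ma=0.0, amplitude_pct=0.0, lfp=lfp)
        thr = cal.initial_duration_threshold(run, BandConfig(15.0), power_thr)
        assert thr == pytest.approx(0.4, rel=0.10)

    def test_too_few_bursts_rejected(self, power_thr):
        p = LfpPlantParams(burst_rate_hz=0.05)
        lfp, _ = synth_lfp(p, 0.0, 30.0, seed=5)
        run = cal.TitrationRun(amplitude_ma=0.0, amplitude_pct=0.0, lfp=lfp)
        with pytest.raises(InsufficientDataError):
            cal.initial_duration_threshold(run, BandConfig(15.0), power_thr,
                                           min_bursts=10)


class TestBurstModulation:
    def test_negative_slope_recovered(self, runs, power_thr):
        _, slope = cal.burst_modulation(runs, BandConfig(15.0), power_thr)
        assert slope < 0
        assert slope == pytest.approx(-LfpPlantParams().k_s_per_ma, rel=0.5)

    def test_amplitude_independent_plant_gives_flat_slope(self, power_thr):
        p = LfpPlantParams(k_s_per_ma=0.0)
        slopes = []
        for rep in range(3):
            runs = []
            for i, amp in enumerate((0.0, 1.5, 3.0, 3.75)):
                lfp, _ = synth_lfp(p, amp, 60.0, seed=700 + 10 * rep + i)
                runs.append(cal.TitrationRun(amplitude_ma=amp,
                                             amplitude_pct=0.0, lfp=lfp))
            slopes.append(cal.burst_modulation(runs, BandConfig(15.0),
                                               power_thr)[1])
        # mean over replicates consistent with zero (per-run SE ~ 0.01 s/mA)
        assert abs(np.mean(slopes)) < 0.02

    def test_two_levels_rejected(self, runs, power_thr):
        with pytest.raises(InsufficientDataError):
            cal.burst_modulation(runs[:2], BandConfig(15.0), power_thr)


class TestTherapeuticWindow:
    def _behaviour_runs(self, behavior, levels=(0, 25, 50, 75, 100, 110),
                        side_effects=None):
        runs = []
        for i, pct in enumerate(levels):
            lfp = TimeSeries(values=np.zeros(10), rate=500.0)
            runs.append(cal.TitrationRun(
                amplitude_ma=CLINICAL * pct / 100.0, amplitude_pct=pct,
                lfp=lfp, behavior=behavior[i],
                side_effect=bool(side_effects[i]) if side_effects else False))
        return runs

    def test_worked_example_selects_75_to_110_percent(self):
        runs = self._behaviour_runs([100, 100, 60, 10, 5, 0])
        w = cal.select_therapeutic_window(runs, CLINICAL)
        assert w.i_min_ma == pytest.approx(0.75 * CLINICAL)
        assert w.i_max_ma == pytest.approx(1.10 * CLINICAL)

    def test_side_effect_caps_i_max(self):
        runs = self._behaviour_runs([100, 100, 60, 10, 5, 0],
                                    levels=(0, 25, 50, 75, 100, 120),
                                    side_effects=[0, 0, 0, 0, 0, 1])
        w = cal.select_therapeutic_window(runs, CLINICAL)
        assert w.i_max_ma < 1.20 * CLINICAL

    def test_no_benefit_anywhere_raises(self):
        runs = self._behaviour_runs([100, 100, 100, 100, 100, 100])
        with pytest.raises(NoWindowError):
            cal.select_therapeutic_window(runs, CLINICAL)

    def test_window_never_exceeds_125_percent_cap(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 8))
            pcts = np.sort(rng.choice(np.arange(0, 126, 5), size=n,
                                      replace=False))
            behavior = np.clip(100 - pcts + rng.normal(0, 10, n), 0, 100)
            behavior[0] = 100.0
            runs = [cal.TitrationRun(amplitude_ma=CLINICAL * p / 100.0,
                                     amplitude_pct=float(p),
                                     lfp=TimeSeries(values=np.zeros(2),
                                                    rate=500.0),
                                     behavior=float(b))
                    for p, b in zip(pcts, behavior)]
            try:
                w = cal.select_therapeutic_window(runs, CLINICAL)
            except NoWindowError:
                continue
            assert w.i_max_ma <= 1.25 * CLINICAL + 1e-9
            assert w.i_min_ma <= w.i_max_ma


class TestEndToEnd:
    def test_calibration_recovers_planted_parameters(self):
        plant = LfpPlantParams(beta_center_hz=18.0)
        runs = _titration_runs(plant=plant, seed=9,
                               behavior=[100, 100, 60, 10, 5, 0])
        res = cal.calibrate_hemisphere(runs, CLINICAL)
        assert res.usable
        assert abs(res.band.center_hz - 18.0) <= 1.0
        assert res.modulation_slope_s_per_ma < 0
        assert res.window is not None
        assert res.window.i_max_ma <= 1.25 * CLINICAL
        # duration threshold close to the plant's law at I_min
        expected = plant.duration_law(res.window.i_min_ma)
        assert res.thresholds.duration_threshold_s == pytest.approx(
            expected, rel=0.15)
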