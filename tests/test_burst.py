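"""Envelope construction, thresholding, burst extraction and streaming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adbskit import burst as bd
from adbskit.burst import (
    BandConfig,
    BurstDetector,
    compute_envelope,
    extract_bursts,
    power_threshold_from_gamma,
)
from adbskit.errors import (
    DegenerateSignalError,
    InsufficientDataError,
    StreamError,
)
from adbskit.signal_io import TimeSeries
from adbskit.synth import LfpPlantParams, synth_lfp

FS = 500.0


def _env_series(values, rate=FS, start=0.0):
    ts = TimeSeries(values=np.asarray(values, float), rate=rate, start_time=start)
    return bd.EnvelopeSeries(series=ts, band=BandConfig(15.0))


def brute_force_bursts(env_values, threshold, rate, start=0.0):
    """Per-sample reference scan used as the independent oracle."""
    events = []
    in_burst = False
    onset = 0
    for i, v in enumerate(env_values):
        if v > threshold and not in_burst:
            in_burst, onset = True, i
        elif v <= threshold and in_burst:
            events.append((start + onset / rate, start + i / rate, False))
            in_burst = False
    if in_burst:
        events.append((start + onset / rate, start + len(env_values) / rate, True))
    return events


class TestEnvelope:
    def test_unit_sinusoid_envelope_near_one(self, sine_500hz):
        env = compute_envelope(sine_500hz, BandConfig(15.0))
        mid = env.values[1000:-1000]
        assert np.all(np.abs(mid - 1.0) < 0.10)

    def test_constant_signal_is_degenerate(self):
        flat = TimeSeries(values=np.zeros(5000), rate=FS)
        with pytest.raises(DegenerateSignalError):
            compute_envelope(flat, BandConfig(15.0))

    def test_amplitude_step_tracked_within_quarter_second(self):
        t = np.arange(int(10 * FS)) / FS
        amp = np.where(t < 5.0, 0.2, 1.0)
        x = TimeSeries(values=amp * np.sin(2 * np.pi * 15 * t), rate=FS)
        env = compute_envelope(x, BandConfig(15.0))
        cross = np.flatnonzero(env.values > 0.5)
        t_cross = cross[cross > int(4.5 * FS)][0] / FS
        assert abs(t_cross - 5.0) < 0.25


class TestGammaThreshold:
    def test_pure_55hz_sinusoid_gives_amplitude_squared(self):
        t = np.arange(int(20 * FS)) / FS
        for a in (1.0, 0.5):
            s = TimeSeries(values=a * np.sin(2 * np.pi * 55 * t), rate=FS)
            assert power_threshold_from_gamma(s) == pytest.approx(a * a, rel=0.10)

    def test_white_noise_threshold_below_mean_gamma_envelope(self, rng):
        s = TimeSeries(values=rng.standard_normal(int(30 * FS)), rate=FS)
        thr = power_threshold_from_gamma(s)
        env = compute_envelope(s, BandConfig(55.0, 20.0))
        assert 0.0 < thr < np.mean(env.values[200:])

    def test_beta_only_signal_gives_small_positive_threshold(self):
        t = np.arange(int(30 * FS)) / FS
        s = TimeSeries(values=np.sin(2 * np.pi * 15 * t), rate=FS)
        thr = power_threshold_from_gamma(s)
        assert 0.0 < thr < 0.01  # filter leakage floor only

    def test_too_short_recording_rejected(self):
        s = TimeSeries(values=np.random.default_rng(0).standard_normal(2000),
                       rate=FS)
        with pytest.raises(Exception):
            power_threshold_from_gamma(s)


class TestExtractBursts:
    def test_constructed_crossing_has_exact_duration(self):
        n = int(5 * FS)
        env = np.full(n, 0.1)
        env[int(2.0 * FS):int(2.3 * FS)] = 1.0
        events = extract_bursts(_env_series(env), 0.5)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(2.0)
        assert events[0].duration_s == pytest.approx(0.300)

    def test_subthreshold_envelope_gives_empty_list(self):
        events = extract_bursts(_env_series(np.full(1000, 0.1)), 0.5)
        assert events == []

    def test_square_wave_matches_brute_force(self):
        env = np.tile(np.r_[np.full(100, 0.1), np.full(150, 2.0)], 10)
        got = extract_bursts(_env_series(env), 1.0)
        ref = brute_force_bursts(env, 1.0, FS)
        assert len(got) == 10
        assert [(e.onset_s, e.offset_s, e.ongoing) for e in got] == ref

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_random_envelopes_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        env = np.abs(np.cumsum(rng.standard_normal(rng.integers(10, 800))))
        thr = float(np.percentile(env, rng.uniform(10, 90)))
        if thr <= 0:
            thr = 0.5
        got = [(e.onset_s, e.offset_s, e.ongoing)
               for e in extract_bursts(_env_series(env), thr)]
        assert got == brute_force_bursts(env, thr, FS)


class TestCurrentBurstDuration:
    def _detector_with_env(self, env):
        det = BurstDetector(band=BandConfig(15.0), power_threshold=0.5, rate=FS)
        det._consume(0, np.asarray(env, float))
        return det

    def test_ongoing_burst_reports_elapsed_time(self):
        env = np.r_[np.full(500, 0.1), np.full(210, 1.0)]
        det = self._detector_with_env(env)
        assert det.current_burst_duration() == pytest.approx(0.42)

    def test_completed_burst_reported_after_it_ends(self):
        env = np.r_[np.full(200, 0.1), np.full(125, 1.0), np.full(500, 0.1)]
        det = self._detector_with_env(env)
        assert det.current_burst_duration() == pytest.approx(0.25)

    def test_no_burst_gives_zero(self):
        det = self._detector_with_env(np.full(400, 0.1))
        assert det.current_burst_duration() == 0.0

    def test_empty_buffer_raises(self):
        det = BurstDetector(band=BandConfig(15.0), power_threshold=0.5, rate=FS)
        with pytest.raises(StreamError):
            det.current_burst_duration()

    def test_burst_older_than_buffer_forgotten(self):
        env = np.r_[np.full(100, 1.0), np.full(int(6 * FS), 0.1)]
        det = self._detector_with_env(env)
        assert det.current_burst_duration() == 0.0


class TestStreaming:
    @pytest.mark.parametrize("chunking", ["50ms", "one_sample", "random"])
    def test_chunked_equals_offline(self, chunking, rng):
        p = LfpPlantParams()
        lfp, _ = synth_lfp(p, 0.0, 20.0, seed=7)
        env = compute_envelope(lfp, BandConfig(15.0))
        thr = 2.5
        offline = [(e.onset_s, e.offset_s) for e in extract_bursts(env, thr)
                   if not e.ongoing and e.onset_s > bd.FIR_ORDER / FS]
        det = BurstDetector(band=BandConfig(15.0), power_threshold=thr, rate=FS)
        if chunking == "50ms":
            sizes = [25] * (len(lfp) // 25)
        elif chunking == "one_sample":
            # single-sample chunks over a short prefix only (slow path)
            lfp = TimeSeries(values=lfp.values[:3000], rate=FS)
            env = compute_envelope(lfp, BandConfig(15.0))
            offline = [(e.onset_s, e.offset_s) for e in extract_bursts(env, thr)
                       if not e.ongoing and e.onset_s > bd.FIR_ORDER / FS]
            sizes = [1] * len(lfp)
        else:
            sizes = []
            left = len(lfp)
            while left:
                n = int(min(left, rng.integers(1, 400)))
                sizes.append(n)
                left -= n
        events, pos = [], 0
        for n in sizes:
            events.extend(det.process(lfp.values[pos:pos + n]))
            pos += n
        events.extend(det.process(lfp.values[pos:]))
        events.extend(det.flush())
        got = [(e.onset_s, e.offset_s) for e in events
               if not e.ongoing and e.onset_s > bd.FIR_ORDER / FS]
        assert got == pytest.approx(offline, abs=1.0 / FS)

    def test_empty_chunk_leaves_state_unchanged(self):
        det = BurstDetector(band=BandConfig(15.0), power_threshold=0.5, rate=FS)
        det.process(np.sin(2 * np.pi * 15 * np.arange(1000) / FS))
        before = (det.samples_seen, det._in_burst, det._n_env)
        assert det.process(np.empty(0)) == []
        assert (det.samples_seen, det._in_burst, det._n_env) == before


class TestBlanking:
    def _detector(self):
        return BurstDetector(band=BandConfig(15.0), power_threshold=0.5, rate=FS)

    def test_burst_bridges_blank_when_still_above_after(self):
        det = self._detector()
        det.blank_interval(1.0, 0.5)
        env = np.r_[np.full(875, 1.0), np.full(125, 0.1)]
        events = det._consume(0, env)
        assert len(events) == 1
        assert events[0].onset_s == 0.0
        assert events[0].offset_s == pytest.approx(1.75)

    def test_burst_ends_at_blank_start_when_below_after(self):
        det = self._detector()
        det.blank_interval(1.0, 0.5)
        env = np.r_[np.full(500, 1.0), np.full(250, 1.0), np.full(250, 0.1)]
        events = det._consume(0, env)
        assert len(events) == 1
        assert events[0].offset_s == pytest.approx(1.0)

    def test_blank_covering_buffer_freezes_duration(self):
        det = self._detector()
        det._consume(0, np.full(500, 1.0))   # ongoing burst, 1 s so far
        det.blank_interval(1.0, 2.0)
        det._consume(500, np.full(1000, 1.0))
        assert det.current_burst_duration() == pytest.approx(1.0)


class TestRecovery:
    def test_mean_duration_monotone_in_threshold_at_operating_levels(self):
        lfp, _ = synth_lfp(LfpPlantParams(), 0.0, 60.0, seed=3)
        env = compute_envelope(lfp, BandConfig(15.0))
        means = []
        for thr in np.linspace(1.5, 7.0, 10):
            ev = [e for e in extract_bursts(env, thr) if not e.ongoing]
            means.append(np.mean([e.duration_s for e in ev]) if ev else 0.0)
        slack = 0.02 * max(means)
        assert all(b <= a + slack for a, b in zip(means, means[1:]))

    def test_planted_mean_duration_recovered_at_snr_3(self):
        p = LfpPlantParams(d0_s=0.4, snr=3.0)
        lfp, truth = synth_lfp(p, 0.0, 120.0, seed=11)
        thr = power_threshold_from_gamma(lfp)
        env = compute_envelope(lfp, BandConfig(15.0))
        ev = [e for e in extract_bursts(env, thr) if not e.ongoing]
        mean = np.mean([e.duration_s for e in ev])
        assert mean == pytest.approx(truth.mean_burst_duration_s, rel=0.15)
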