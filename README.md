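# adbskit

Simulation and analysis toolkit for **beta burst-duration driven adaptive
deep brain stimulation (aDBS)** in Parkinson's disease, built for
controls engineers and movement-disorder researchers who want to exercise
the full closed-loop stack — neural biomarker, control policy,
calibration and behavioural outcome metrics — entirely on synthetic,
ground-truth-labelled signals.

## What it implements

**Biomarker.** Subthalamic LFP (500 Hz) is band-passed with a 128-order
FIR around a participant-specific 6 Hz band inside the beta range
(13–30 Hz), squared, and peak-interpolated into a beta envelope.  A
*burst* is a maximal run of the envelope above a power threshold θ; the
threshold is the mean trough value of the same envelope computed in the
45–65 Hz band on an OFF-stimulation recording.  The controller reads the
*current burst duration* d(t): the ongoing suprathreshold period if one
is active, otherwise the most recent completed one.

**Control policy.** A single duration threshold τ drives bang-bang
control with asymmetric rate limits:

    I(t+Δ) = clip( I(t) + 0.1 mA · sign(d(t) − τ),  I_min,  I_max )

with sustained ramps limited to 0.1 mA/s up and 0.05 mA/s down (down is
half of up, biasing stimulation upward), steps of 0.1 mA, and the
therapeutic window [I_min, I_max] capped at 125% of the clinical
amplitude.  Stimulation constants (140.1 Hz, 60 µs) are fixed.  Each
hemisphere runs independently; detectors are blanked after every step to
skip the stimulation-change artifact.  Control conditions: constant
clinical stimulation (cDBS) and a TEED-matched randomly adapting control
(rDBS) built by shuffling the dwell segments of a recorded adaptation
pattern (TEED ∝ ∫ I² f · pw dt at unit impedance).

**Calibration.** From stimulation titrations (25–125% of clinical): Welch
spectra (1 s Hann, 50% overlap), beta-peak selection by strongest
burst-duration modulation with amplitude, the initial τ as the mean burst
duration OFF or at I_min, and the therapeutic window from a behavioural
metric (percent time freezing) under explicit benefit/tolerance rules.

**Outcome metrics.** Stepping-in-place force plates (1000 Hz): gait-cycle
segmentation, swing/stride times,
asymmetry = 100·|ln(shorter/longer mean swing time)|,
arrhythmicity = mean stride-time CV, and force-plate freeze detection
(no full excursion below 15% / above 85% body weight).  Shank IMUs
(128 Hz): sagittal extraction by PCA after a zero-phase 8th-order 9 Hz
Butterworth, stride segmentation, mean peak angular velocity, and a
logistic freeze-probability model (features: 6-step arrhythmicity and
asymmetry, last stride time, last swing angular range; freeze when
p > 0.7).  Wrist flexion-extension: V_rms and cycles/s after a zero-phase
4th-order 4 Hz Butterworth.

**Plant.** A stimulation-dependent LFP generator (1/f background, gated
beta bursts whose mean duration shrinks linearly with amplitude, gamma
floor, artifact transients) plus force-plate, shank-IMU and wrist
generators with plantable freezes — every generator returns its ground
truth, so recovery is testable end to end.

## Worked example

Generate one minute of synthetic LFP, derive the power threshold from the
recording itself, and extract bursts:

```bash
adbskit simulate lfp --seed 3 --duration 60 --out-prefix demo
adbskit detect-bursts --lfp demo_lfp.csv --center 15 \
    --off-lfp demo_lfp.csv --out demo_bursts.csv
```

```json
{
  "power_threshold": 2.6856428027360297,
  "n_bursts": 31,
  "mean_duration_s": 0.4280645161290798,
  "median_duration_s": 0.3580000000000396
}
```

The threshold (≈2.69, envelope units) sits between the between-burst beta
envelope and the burst envelope, so the 31 detected bursts track the
planted ones; their mean duration (0.43 s) reflects the generator's OFF
duration law (0.5 s mean minus edge effects).  Now close the loop for
300 s with τ = 0.35 s inside a [1.0, 3.5] mA window:

```bash
adbskit run-loop --mode adbs --config config.json --duration 300 --seed 2
```

```json
{
  "burst_stats": {"L": {"n": 140, "mean_duration_s": 0.274}},
  "teed": {"L": 9.04},
  "mean_amplitude_ma": {"L": 1.81}
}
```

The controller settles near the amplitude where the plant's burst
durations cross τ (here ≈2 mA as the run approaches steady state —
mean 1.81 mA includes the initial ramp from I_min), and on-stimulation
bursts are shorter (0.27 s) than OFF (0.43 s): the closed loop shortens
bursts, which is the behaviour the policy is designed to produce.

Other entry points: `adbskit calibrate`, `adbskit analyze-sip`,
`adbskit analyze-tbc`, `adbskit analyze-wrist`, and
`adbskit run-experiment` for the four-condition (OFF/cDBS/aDBS/rDBS)
comparison with per-condition metric summaries.

## Layout

```
src/adbskit/
  signal_io.py        time series, FIR/Butterworth filters, Welch PSD, CSV I/O
  burst.py            beta envelope, power threshold, offline + streaming bursts
  controller.py       policy, ramp limits, window, cDBS/rDBS, TEED
  calibration.py      titration spectra, band selection, thresholds, window
  gait_kinetics.py    force-plate gait cycles, asymmetry/arrhythmicity, freezes
  gait_kinematics.py  IMU sagittal extraction, strides, logistic freezes, wrist
  synth.py            LFP plant and gait/wrist generators with ground truth
  experiment.py       calibrate + run all four conditions + report
  cli.py              `adbskit` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
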