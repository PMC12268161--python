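# Methods

This note documents the models, parameter choices and numerical
conventions behind `adbskit`, and what the synthetic-signal tests do and
do not establish about real recordings.

## Burst detection

The detection chain is: causal 128-order windowed-sinc (Hamming) FIR
bandpass → square → strict local maxima of the squared signal (a flat
plateau contributes its last sample) → linear interpolation between
successive maxima, holding the nearest maximum before the first and
after the last.  The FIR is normalised to unity gain at the band centre;
with a 6 Hz band at 500 Hz the transition bands are wider than the
passband, so gain at the band edges is ≈0.7 — the envelope of a
centre-frequency oscillation is unbiased, off-centre oscillations are
attenuated.  Both offline and streaming paths share one incremental
implementation, so they agree sample-exactly for any chunking; the only
excluded region is the FIR warm-up (128 samples).  Burst onsets/offsets
live on the sample grid (2 ms at 500 Hz); sub-sample interpolation would
be spurious given the envelope is itself an interpolation.

The power threshold is the mean of the strict local minima of the
45–65 Hz envelope of an OFF recording (same FIR pipeline, centre 55 Hz,
width 20 Hz, one code path for both bands).  A perfectly flat envelope
has no strict minima; in practice incommensurate sampling always
produces them.  At least 10 s of OFF data and 10 minima are required.

Streaming state: the detector holds a 5 s buffer notion for the
"most recent burst" — a completed burst older than 5 s reads as 0.
Blanking excludes samples in a span from burst logic; a burst ongoing at
blank start is *held*: the first post-blank sample either continues it
(the burst spans the blank) or closes it with its offset at the blank
start.  While a blank is undecided the reported current duration is
frozen at its pre-blank value.

A caveat on thresholds: the mean detected duration is *not* strictly
monotone in the power threshold — raising the threshold both shortens
surviving bursts and drops short ones from the mean, and the second
effect can raise it.  In the operating regime (thresholds at or above
the trough-derived value) monotonicity holds to within ~2%, and the
property test asserts exactly that.

## Control policy

Decisions are made once per second per hemisphere (the default matches
the 0.1 mA step at 0.1 mA/s so every up-decision can execute).
`decide` increments only when the current burst duration strictly
exceeds τ; ties decrement.  Rate limiting is a minimum interval between
*executed* steps of step/rate for the requested direction (1 s up, 2 s
down at defaults), which yields exactly the sustained 0.1/0.05 mA/s
ramps.  Saturation at the window edges is silent but logged.  The
initial amplitude is I_min: conservative, inside the window, and
consistent with the upward ramp bias.

TEED is a unit-impedance proxy, Σ I²·f·pw·Δt with I in mA; only ratios
and differences between conditions are meaningful.

**rDBS.** The random control condition shuffles the *dwell segments* of
the source adaptive run: the amplitude trace is cut at every executed
step and the constant-amplitude pieces are uniformly permuted.  This
preserves the amplitude distribution over the run exactly — hence TEED,
the window bounds and the quantised levels — while destroying the
biomarker coupling.  (Shuffling step *directions* instead does not
preserve TEED even approximately: the permuted walk visits different
amplitudes, and window clamping compounds the mismatch.  We measured
median 17% TEED error with that construction, which would defeat the
purpose of an energy-matched control.)  A consequence: jumps between
consecutive shuffled segments may exceed one step; the trace remains
quantised and inside the window.

## Calibration

Beta peaks are local PSD maxima in 13–30 Hz rising ≥3 dB above a
log-log linear background fitted over 5–45 Hz excluding 13–30 Hz.  Among
candidate peaks, the 6 Hz band whose mean burst duration has the most
negative least-squares slope against amplitude (mA) wins.  The initial
duration threshold is the mean completed-burst duration of the OFF run,
or of the run nearest I_min when a therapeutic window is available — the
latter is the default in the end-to-end pipeline because a threshold at
the OFF mean leaves the controller pinned at I_min (bursts at I_min are
already shorter than OFF).  Window rules are explicit and configurable:
benefit = behavioural metric at or below half the OFF value (or more
than 50 points below it), tolerance = within 10 points of the best
level; I_max additionally requires no side-effect flag and is capped at
125% of clinical.  A floor parameter stands in for the tremor-dominant
adjustment, which is clinician judgement, not a computation.

## Gait and wrist metrics

Force plates: forces are normalised to percent body weight (estimated as
the mean total vertical force when not given).  Cycle segmentation uses
a 20% BW unload threshold with a 50 ms debounce; the freeze rule uses
15%/85% (a *full excursion* = one foot below 15% while the other is
above 85%), with freezes = spans ≥1 s containing no excursion, merged
across <0.2 s gaps.  The two thresholds differ deliberately: 20% for
events reduces chatter, 15/85 encodes "feet never fully lift off".
Sample standard deviation (n−1) is used in the stride-time CV.
Metrics on fully frozen trials are undefined and flagged, not zeroed.
Stride lists on partially frozen trials include the stride spanning the
freeze, so arrhythmicity grows sharply with freezing — intended
behaviour, not an artifact to be filtered.

IMU: axes are low-passed (zero-phase Butterworth, stated order applied
forward–backward, reflect padding of 3× the order) before PCA; the
first principal axis is the sagittal plane, the sign chosen so swing
peaks are positive, and the explained-variance fraction is reported as a
confidence signal.  Mid-swings are positive peaks above 0.4× the 95th
percentile of positive samples (scale-free across slow and fast
walkers); swings span the nearest zero crossings; swing angular range is
the time-integral of angular velocity over the swing.  The logistic
freeze model pools steps across legs ordered by mid-swing time, uses a
6-step rolling window (carrying forward arrhythmicity/asymmetry when a
window lacks a leg), standardises features, and flags steps with
p > 0.7; its coefficients are fitted by maximum likelihood on a labelled
synthetic corpus with a 30% held-out AUROC report.  Wrist cycles/s
counts positive-going zero crossings of the demeaned filtered signal
(demeaning gives gyro-drift immunity).

## The LFP plant

The background is unit-variance noise shaped to a 1/f^α spectrum
(α = 1 default) by a cascade of eight first-order pole/zero sections
log-spaced over 0.4–120 Hz.  Bursts are raised-cosine-gated (50 ms
edges) sinusoids at the band centre; the planted duration is the gate's
full width at half maximum.  New bursts start with exponential waiting
times (hazard 0.8 /s when idle) and durations are gamma (shape 4) with
mean `max(0.1 s, 0.5 s − 0.075 (s/mA) · I)` evaluated at the amplitude
applied when the burst starts — a linear-with-floor law chosen for
testability; the true amplitude→duration mapping is unknown beyond its
direction.  Two modelling choices matter and are deliberate:

* **Bursts replace, not add to, the in-band background.**  During a
  burst the background's own beta-band component (isolated by the same
  linear-phase FIR, with the wideband path delayed to match) is
  cross-faded out as the oscillation fades in, reflecting transient
  synchronization of one population.  Without this, beating between the
  oscillation and independent in-band noise splits detected bursts at
  any threshold.
* **Burst amplitude is `snr` × the broadband background RMS** (default
  3), and the 45–65 Hz floor (`gamma_noise_rms`, default 2.1) is set so
  the trough-derived threshold lands near half the burst envelope
  power — above the between-burst beta envelope, below the burst
  plateau.  That is the operating point the trough-threshold procedure
  is meant to find; with the floor far lower the threshold drowns in
  background crossings, far higher it clips bursts.

Stimulation changes add an additive exponential transient (peak 10× the
burst amplitude, τ = 100 ms) — enough to corrupt an unblanked detector,
which is what the blanking mechanism is for.  Separate RNG streams for
background, gamma floor and burst scheduling make the emitted signal
invariant to chunk size, so the closed-loop plant and the open-loop
generator agree bit-for-bit.

## Behavioural generators and linkage

The stepping generator moves a left-load fraction w(t) through
0.5 → 0 (left swing) → 0.5 → 1 (right swing) → 0.5 with raised-cosine
transitions timed so the time below the 20% crossing equals the planted
swing time; freezes replace stepping with 5 Hz trembling at 30–70% BW or
a static 50/50.  The shank generator plants sin² velocity pulses on a
stance baseline balanced so the stride-mean angular velocity is ≈0 (the
shank returns to its orientation each stride); freezes are small
(150 deg/s), short, irregular shuffling pulses — festination-like, and
deliberately above the step detector's threshold so frozen periods still
produce (abnormal) steps for the logistic model to classify.

The condition experiment links neural state to behaviour through an
explicit simulation device: the time-average of the plant's duration law
over a condition's amplitude trace sets freeze fraction, stride CV,
swing asymmetry, shank vigour and wrist amplitude through logistic maps.
With the linkage gain at zero all conditions are indistinguishable by
construction.  This linkage is a test harness, not a physiological
claim.

## Problem sizes and determinism

Closed-loop tests use 600 s runs at 500 Hz (20 seeds in the test suite,
12 in the acceptance script), titrations 40–60 s per level, gait trials
100–120 s — sizes at which every recovery tolerance has a few-sigma
margin.  Every stochastic component takes an explicit seed; hypothesis
property tests run derandomised.

## What passing tests show — and do not

The synthetic signals have clean separations real data lack: the burst
oscillation is a pure sinusoid with known amplitude, the gamma floor is
elevated and stationary, gait transitions are noiseless raised cosines,
and freezes are planted as crisp intervals.  Passing recovery tests
therefore validates the *implementation* — that the pipeline measures
what it defines, that streaming equals offline, that the controller
respects its safety envelope, that TEED matching is exact — not clinical
performance.  Real LFP has nonstationary floors, movement artifacts and
non-sinusoidal bursts; real freezing lacks a ground-truth boundary.  The
freeze-model coefficients shipped here are fitted to the synthetic
corpus and are not transferable to patient data.
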