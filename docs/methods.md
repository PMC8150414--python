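# Methods

This note documents the models and procedures implemented in `bandecg`,
the parameter choices that matter, and what the synthetic validation does
and does not demonstrate.

## Problem setting

A chest/waist-worn single-lead ECG sampled at a nominal 125 samples/s
(16-bit ADC) reaches the recording device over Bluetooth. The recording
carries three characteristic defects: irregular sample timing (transport
jitter), contiguous gaps (burst packet loss), and large low-frequency
baseline excursions from respiration and electrode movement. The goal is a
beat-to-beat heart-rate estimate that is robust to all three, plus the
standard statistics for validating the device against a reference system.

## Pipeline stages and parameter choices

### Resampling (telemetry → uniform signal)

Irregular arrival-timestamped samples are interpolated onto a uniform
1 kHz grid spanning exactly the record's time span. **Linear**
interpolation is the default: it is exact on affine segments, cannot
overshoot (important ahead of a squaring stage), and is monotonicity
preserving; cubic splines are available via configuration. Duplicate
timestamps (Bluetooth batch arrivals) keep the last value with a warning.
Gaps of any length are interpolated — beats lost in long gaps are handled
later at the RR-interval level, where the information to repair them
actually exists.

### Baseline removal

A 2nd-order Butterworth high-pass at 0.5 Hz, run forward–backward
(`sosfiltfilt`) so the realized magnitude is |H|² and the phase is zero —
beat fiducials are not shifted. 0.5 Hz matches the lower edge of the ECG
band used by the band-pass stage. Boundary handling uses the *even*
(mirror) signal extension: the default odd extension inverts a QRS sitting
on the record boundary and produces a step transient large enough to
corrupt the first detected beat.

### Band-pass

A 31-tap (order 30) Hamming-windowed-sinc FIR with nominal 0.5–35 Hz
passband, applied at the post-interpolation rate (1 kHz). The taps are
symmetric (linear phase); the constant group delay of 15 samples is
removed by centred convolution over a reflect-padded input, so the output
is time-aligned with the input to machine precision (verified by the
impulse-response test).

**Known limitation:** 31 taps at 1 kHz give a very wide transition band —
the realized response at 0.5 Hz is nowhere near a brick wall, and most of
the actual baseline rejection is carried by the IIR stage. The tests
therefore check the *realized* tap response (closed-form
|Σ h_k e^{−j2πfk/fs}|, matched within 1% by a lock-in measurement on
sines), not an idealized specification. The filter order and rate are
configurable for sensitivity analysis.

### QRS detection (Pan–Tompkins)

Implemented from scratch on the band-passed signal with the classic
constants, all exposed in the detector parameter map and logged per run:

* 5-point centred derivative, pointwise squaring, 150 ms moving-window
  integration (centred window → zero stage delay);
* adaptive thresholds: THRESHOLD = NPK + 0.25·(SPK − NPK), with running
  updates SPK ← 0.125·peak + 0.875·SPK on signal peaks and the analogous
  update for NPK on noise peaks; initialization from the first 2 s
  (SPK = 0.25·max, NPK = 0.5·mean of the integrated signal, capped at
  SPK/2);
* search-back: a gap exceeding 1.66× the mean of the last 8 accepted RRs
  is rescanned at half threshold (search-back acceptances update SPK with
  the faster 0.25 memory);
* T-wave discrimination: a candidate within 360 ms of the previous beat is
  rejected if its maximal integrated-signal slope is below half the
  previous beat's;
* fiducial refinement: accepted beats move to the local extremum of the
  band-passed signal (in the record's dominant R polarity) within ±75 ms.
  Using the dominant polarity rather than |x| prevents a deep S wave from
  capturing the fiducial near record boundaries;
* a 200 ms refractory period is enforced both at candidate selection and
  again after refinement.

Because all thresholds are derived from the signal itself, detection is
invariant to positive amplitude scaling (tested). Candidate peaks are
found with ±∞ sentinels at the record ends so a beat lying exactly on the
boundary is still detectable.

### RR-interval correction (lost-beat reconstruction)

An interval R is **abnormal** when R > max(1500 ms, 1.5 × local mean).
1500 ms is the printed exemplar of an out-of-range beat interval; the
relative clause keeps the rule meaningful at high heart rates, where a
dropout shorter than 1500 ms already spans multiple beats. The local mean
is the mean of the last 8 non-abnormal intervals, seeded by the series
median. The number of lost beats is estimated as k = round(R / local
mean), k ≥ 2 — raised further in the rare case an equal split would itself
remain abnormal — and R is replaced by k equal sub-intervals whose sum is
exactly R (the last sub-interval absorbs float rounding), so total
recording duration is conserved and correction is idempotent. If an
abnormal interval is encountered before any normal one and the series
median itself exceeds the absolute threshold, the series is declared
uncorrectable rather than silently rewritten.

Merging of abnormally *short* intervals (false detections) into their
successor is implemented but disabled by default; the lost-beat rule alone
is the default behaviour.

### Heart rate and smoothing

HR_i = 60000 / RRI_i bpm, stamped at the end time of each interval. The
magnitude of beat-timing noise this leaves: at a true 72 bpm
(RRI = 833.33 ms), one fiducial displaced by 50 ms moves the one-interval
HR by up to 60000/783.33 − 72 ≈ 4.6 bpm. The reported rate is therefore a
5-point moving average; the default window is **trailing** (mean of the
current and previous 4 beats), which is causal and suited to reporting the
current rate — a centred mode is available. Leading outputs average all
available points, so the output length equals the input length. A moving
average is a contraction in variance (tested property).

### Agreement statistics

Error convention is **device − reference** (printed in every report). MAE
= mean |error|; MAPE = 100 · mean(|error| / reference); mean ± SD uses the
n−1 denominator; limits of agreement are mean ± 1.96·SD of the differences
and, in ratio form, of device/reference; Pearson r is computed on the raw
pairs and reported as NaN when either side is constant. Pairing is by
linear interpolation of both series onto a shared 1 s grid over their
temporal overlap. All formulas are verified against an independently coded
two-pass loop implementation to 1e−12 relative.

## Synthetic data: what it emulates, what it does not

* **Beat times** integrate an instantaneous-rate profile (constant, linear
  ramp, sinusoidal modulation) by forward stepping
  t_{i+1} = t_i + 60000/HR(t_i), bounded to (20, 250) bpm.
* **Morphology** is the standard sum-of-Gaussians parameterization: upright
  R 1.0 mV (σ = 6 ms), P 0.15 mV at −180 ms (σ = 25 ms), Q −0.1 mV at
  −25 ms, S −0.2 mV at +25 ms, T 0.3 mV at +280 ms (σ = 60 ms) — chosen so
  a clear P-QRS-T complex is visible at the device's resolution; all
  configurable.
* **Baseline wander** defaults to a 0.3 mV sinusoid at 0.2 Hz (respiratory
  band); **noise** is white Gaussian.
* **Channel**: resampling to 125 samples/s, quantization to 16 bits over a
  10 mV full-scale range (LSB ≈ 0.15 µV; error bounded by half a step,
  tested), zero-mean Gaussian timestamp jitter with a monotonicity clamp,
  and burst loss modelled as per-sample Bernoulli burst starts with
  geometric burst lengths — the simplest process producing contiguous
  dropouts. Channel parameters are chosen for test coverage; no claim is
  made that they match any particular radio's statistics.

What passing the synthetic suites does **not** show: performance on real
recordings. The generator has stationary Gaussian noise, a strictly
periodic wander, fixed morphology, and no motion artifacts, electrode
drop-outs, ectopic beats or polarity changes — all present in wearable
data. Agreement numbers computed on synthetic data characterize the
algorithm chain, not the physical device.

## Validation conditions and problem sizes

The standing validation conditions, fixed in the acceptance suite and
`scripts/acceptance.py`:

* end-to-end recovery: 5-minute record, heart rate ramping 60→105 bpm,
  noise SD 0.05 mV, wander 0.3 mV @ 0.2 Hz, jitter SD 2 ms, burst loss
  probability 0.005 with mean burst 5 samples; pipeline MAPE against the
  ground-truth-derived (identically smoothed) HR series must be ≤ 3%;
* detection: clean 60 s records at 40, 60, 72, 120 and 180 bpm,
  sensitivity = PPV = 1.0 at ±20 ms;
* reconstruction: 5% isolated deletions from a 72 bpm train recovered to
  within 1 ms with exact duration conservation;
* filters, resampling and statistics as described above.

These sizes keep the whole suite and the acceptance script well under a
minute while leaving each measurement far from its tolerance.

## Numerical notes

* All times are milliseconds end-to-end; sampling rates are Hz.
* The resampling grid is anchored at the first arrival time; no output
  sample lies outside the record span (no extrapolation).
* Duration conservation in RRI correction and LoA reconstruction identities
  hold to 1e−9 relative or better.
* Every stochastic component (noise, jitter, loss, test perturbations)
  draws from an explicitly seeded `numpy` generator; pipeline results are
  bit-identical under a fixed config and input.
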