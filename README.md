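# bandecg

Heart-rate estimation from waistband wearable-ECG telemetry.

A waistband-worn single-lead ECG unit samples at 125 samples/s with a
16-bit ADC and streams samples to a phone over Bluetooth. The recorded
stream is irregular: arrival-time jitter and burst packet loss corrupt the
sample spacing, the loosely coupled textile electrode picks up strong
baseline wander, and a missed or spurious QRS detection can throw the
beat-to-beat heart rate off by several bpm. `bandecg` implements the full
processing chain that turns such a stream into a reliable heart-rate trace,
plus the statistics used to validate one heart-rate device against another.

**Pipeline** (in order):

1. **Resampling** — the irregular stream is linearly interpolated onto a
   uniform 1 kHz grid to compensate for uneven received spacing.
2. **Baseline removal** — a 2nd-order Butterworth high-pass (0.5 Hz),
   applied forward–backward for zero phase.
3. **Band-pass** — a 30th-order (31-tap) linear-phase FIR filter with a
   0.5–35 Hz passband, group delay compensated.
4. **QRS detection** — a from-scratch Pan–Tompkins detector: 5-point
   derivative → squaring → 150 ms moving-window integration → adaptive
   dual thresholds with search-back and T-wave discrimination.
5. **RR intervals and lost-beat reconstruction** — RRI_i = R_{i+1} − R_i;
   an interval R > max(1500 ms, 1.5 × local mean) is treated as hiding
   lost beats and replaced by k = round(R / local mean) equal sub-intervals
   summing to R exactly.
6. **Heart rate** — HR_i = 60000 / RRI_i bpm, smoothed with a 5-point
   (trailing) moving average.

**Agreement statistics** for device validation: MAE, MAPE, mean error ± SD,
Bland–Altman 95% limits of agreement (mean ± 1.96 SD, in both difference
and device/reference-ratio form) and Pearson r, on pairs aligned to a
shared 1 s grid.

**Synthetic data** — because every stage needs ground truth to be testable,
the package ships a generator: beat times from a constant / ramp /
sinusoidal heart-rate profile, P-QRS-T morphology as five Gaussian waves
per beat, respiratory baseline wander, white noise, and a channel emulator
(125 sps resampling, 16-bit quantization, Gaussian timestamp jitter, burst
packet loss) — all deterministic under a seed.

## Worked example

```python
import bandecg as be

# 2 min of ECG, heart rate oscillating 75 ± 8 bpm, with noise,
# baseline wander, 2 ms Bluetooth jitter and burst packet loss
cfg = be.SynthConfig(duration=120, hr_profile=be.SinusoidalHR(75, 8, 30),
                     noise_sd=0.05, seed=0)
truth = be.generate_beat_times(cfg)
stream = be.channel_emulate(
    be.synth_ecg(truth, cfg),
    be.ChannelConfig(jitter_sd=2.0, loss_prob=0.005, seed=0))

result = be.run_pipeline(stream)             # full chain
reference = be.smooth_hr(be.hr_from_rri(be.compute_rri(truth)), 5)
report = be.agreement_stats(be.align_hr(result.hr_smoothed, reference,
                                        condition_label="bench"))
print(report.to_text())
```

prints

```
Agreement report (bench); error = device - reference
  n pairs            : 119
  mean HR device     : 74.57 bpm
  mean HR reference  : 75.13 bpm
  MAE                : 0.58 bpm
  MAPE               : 0.71 %
  mean error (SD)    : -0.56 (1.94) bpm
  LoA (difference)   : -4.36 to 3.24 bpm
  ratio mean         : 0.9931
  LoA (ratio)        : 0.9462 to 1.0400
  Pearson r          : 0.936
```

Despite the channel dropping bursts of samples (146 of 150 beats were
detected directly; 4 intervals were reconstructed), the smoothed heart
rate tracks ground truth to well under 1% mean absolute percentage error,
and the Bland–Altman limits show individual 1-s readings agreeing within
about ±4 bpm.

The same chain is scriptable from a shell:

```sh
bandecg synth --duration 60 --bpm 72 --out raw.csv --truth beats_truth.csv
bandecg run   --in raw.csv --out results/
bandecg agree --device results/hr.csv --reference ref_hr.csv --out report.json
```

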