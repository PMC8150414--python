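"""Synthetic ECG and wireless-channel simulation.

No recordings ship with the package, so every pipeline stage is exercised
against generated data with known ground truth:

* beat times from an instantaneous heart-rate profile (constant, linear
  ramp, or sinusoidal modulation), stepped as t_{i+1} = t_i + 60000/HR(t_i);
* an ECG trace built per beat from five Gaussian bumps (P, Q, R, S, T) —
  the standard synthetic-ECG parameterization — plus a respiratory-band
  baseline sinusoid and white Gaussian noise;
* a channel model reproducing the wearable acquisition chain: resampling
  to the device's 125 samples/s, 16-bit quantization over the ADC
  full-scale range, zero-mean Gaussian arrival-time jitter with a
  monotonicity clamp, and burst packet loss (per-sample Bernoulli burst
  starts with geometric burst lengths).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .qrs import BeatAnnotations
from .telemetry import ADC_MAX, ADC_MIN, TelemetryStream, UniformSignal

HR_MIN, HR_MAX = 20.0, 250.0


# ---------------------------------------------------------------- profiles
@dataclass
class ConstantHR:
    bpm: float

    def rate(self, t_ms: float) -> float:
        return self.bpm


@dataclass
class RampHR:
    """Linear ramp from start_bpm to end_bpm across the record duration."""

    start_bpm: float
    end_bpm: float
    duration_s: float

    def rate(self, t_ms: float) -> float:
        frac = min(max(t_ms / (self.duration_s * 1000.0), 0.0), 1.0)
        return self.start_bpm + frac * (self.end_bpm - self.start_bpm)


@dataclass
class SinusoidalHR:
    mean_bpm: float
    amplitude_bpm: float
    period_s: float

    def rate(self, t_ms: float) -> float:
        return self.mean_bpm + self.amplitude_bpm * np.sin(
            2 * np.pi * t_ms / (self.period_s * 1000.0)
        )


# ------------------------------------------------------------------ config
#: per-wave (amplitude mV, Gaussian width/sigma ms, offset from R ms)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 25.0, -180.0),
    "Q": (-0.10, 6.0, -25.0),
    "R": (1.00, 6.0, 0.0),
    "S": (-0.20, 6.0, 25.0),
    "T": (0.30, 60.0, 280.0),
}


@dataclass
class SynthConfig:
    """Ground-truth ECG generator settings.

    duration : record length, seconds
    hr_profile : ConstantHR | RampHR | SinusoidalHR
    wave_params : {wave: (amplitude mV, width ms, offset-from-R ms)}
    baseline_wander : (amplitude mV, frequency Hz) respiratory drift
    noise_sd : white-noise SD, mV
    """

    duration: float = 60.0
    hr_profile: object = field(default_factory=lambda: ConstantHR(72.0))
    wave_params: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    baseline_wander_amplitude: float = 0.3   # mV
    baseline_wander_freq: float = 0.2        # Hz
    noise_sd: float = 0.0                    # mV
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if any(w[1] <= 0 for w in self.wave_params.values()):
            raise ConfigurationError("wave widths must be positive")


@dataclass
class ChannelConfig:
    """Acquisition-chain emulation settings (device defaults: 125 sps,
    16-bit ADC over a 10 mV full-scale range)."""

    device_rate: float = 125.0
    adc_bits: int = 16
    adc_range: float = 10.0        # mV, full scale (symmetric about 0)
    jitter_sd: float = 0.0         # ms
    loss_prob: float = 0.0         # burst-start probability per sample
    burst_length_mean: float = 5.0 # samples
    seed: int = 0

    def __post_init__(self):
        if self.device_rate <= 0:
            raise ConfigurationError("device_rate must be positive")
        if not 0 <= self.loss_prob < 1:
            raise ConfigurationError("loss_prob must be in [0, 1)")
        if self.burst_length_mean < 1:
            raise ConfigurationError("burst_length_mean must be >= 1 sample")

    @property
    def lsb(self) -> float:
        """One ADC step in mV."""
        return self.adc_range / 2 ** self.adc_bits


# -------------------------------------------------------------- generators
def generate_beat_times(config: SynthConfig) -> BeatAnnotations:
    """Integrate the heart-rate profile into ground-truth beat times.

    Beats start at t = 0; each next beat follows after 60000/HR(t) ms.
    Deterministic given the config; a profile leaving (20, 250) bpm raises
    :class:`ConfigurationError`.
    """
    t = 0.0
    end = config.duration * 1000.0
    beats: list[float] = []
    while t < end:
        hr = float(config.hr_profile.rate(t))
        if not HR_MIN < hr < HR_MAX:
            raise ConfigurationError(f"HR profile leaves ({HR_MIN}, {HR_MAX}) bpm: {hr}")
        beats.append(t)
        t += 60000.0 / hr
    return BeatAnnotations(np.asarray(beats), source="truth")


def synth_ecg(
    beats: BeatAnnotations, config: SynthConfig, render_rate: float = 1000.0
) -> UniformSignal:
    """Render an ECG trace (mV) from beat times.

    Each beat contributes five Gaussian bumps at the configured offsets,
    amplitudes and widths; the R peak of each beat sits at its beat time in
    the noiseless case.  Baseline wander and seeded Gaussian noise are
    added on top.
    """
    if len(beats) > 1 and np.any(np.diff(beats.beat_times) <= 0):
        raise ValidationError("beat times must be strictly increasing")
    min_width = min(w[1] for w in config.wave_params.values())
    if min_width < 2 * 1000.0 / render_rate:
        raise ConfigurationError(
            "render_rate too low to resolve the narrowest wave (width < 2 samples)"
        )
    n = int(round(config.duration * render_rate)) + 1
    t = 1000.0 / render_rate * np.arange(n)  # ms
    sig = np.zeros(n)
    for b in beats.beat_times:
        for amp, width, offset in config.wave_params.values():
            centre = b + offset
            lo = np.searchsorted(t, centre - 5 * width)
            hi = np.searchsorted(t, centre + 5 * width)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / width) ** 2)
    if config.baseline_wander_amplitude:
        sig += config.baseline_wander_amplitude * np.sin(
            2 * np.pi * config.baseline_wander_freq * t / 1000.0
        )
    if config.noise_sd:
        rng = np.random.default_rng(config.seed)
        sig += rng.normal(0.0, config.noise_sd, n)
    return UniformSignal(render_rate, 0.0, sig, unit_label="mV")


def burst_loss_mask(
    n: int, loss_prob: float, burst_length_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask for the burst-loss model: each sample starts a
    dropped burst with probability ``loss_prob``; burst lengths are
    geometric with the given mean (support >= 1)."""
    keep = np.ones(n, dtype=bool)
    starts = np.flatnonzero(rng.random(n) < loss_prob)
    p_geo = 1.0 / burst_length_mean
    for s in starts:
        length = int(rng.geometric(p_geo))
        keep[s : s + length] = False
    return keep


def channel_emulate(sig: UniformSignal, config: ChannelConfig) -> TelemetryStream:
    """Emulate the wearable acquisition chain on a rendered ECG.

    The signal is resampled to ``device_rate``, quantized to
    ``adc_bits`` over ``adc_range`` (clipped to the signed 16-bit span),
    timestamps are perturbed by zero-mean Gaussian jitter with a clamp that
    keeps them strictly increasing, and contiguous bursts are dropped per
    the loss model.  Deterministic given ``config.seed``.
    """
    if config.device_rate > sig.sampling_rate:
        raise ConfigurationError("device_rate exceeds the rendered signal rate")
    rng = np.random.default_rng(config.seed)
    step_ms = 1000.0 / config.device_rate
    n_dev = int(np.floor(sig.duration_ms / step_ms)) + 1
    dev_t = sig.start_time + step_ms * np.arange(n_dev)
    dev_v = np.interp(dev_t, sig.times, sig.values)

    counts = np.clip(np.round(dev_v / config.lsb), ADC_MIN, ADC_MAX).astype(np.int64)

    if config.jitter_sd > 0:
        jittered = dev_t + rng.normal(0.0, config.jitter_sd, n_dev)
        eps = 1e-6
        # monotonicity clamp: never earlier than the previous arrival
        ramp = eps * np.arange(n_dev)
        jittered = np.maximum.accumulate(jittered - ramp) + ramp
    else:
        jittered = dev_t

    if config.loss_prob > 0:
        keep = burst_loss_mask(n_dev, config.loss_prob, config.burst_length_mean, rng)
    else:
        keep = np.ones(n_dev, dtype=bool)

    return TelemetryStream(
        times=jittered[keep],
        values=counts[keep],
        nominal_rate=config.device_rate,
        meta={"channel": {
            "jitter_sd": config.jitter_sd,
            "loss_prob": config.loss_prob,
            "burst_length_mean": config.burst_length_mean,
            "seed": config.seed,
        }},
    )
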