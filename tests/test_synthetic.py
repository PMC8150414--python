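import numpy as np
import pytest

from bandecg.errors import ConfigurationError
from bandecg.preprocess import preprocess
from bandecg.qrs import detect_qrs, score_detection
from bandecg.synthetic import (
    ChannelConfig,
    ConstantHR,
    RampHR,
    SinusoidalHR,
    SynthConfig,
    burst_loss_mask,
    channel_emulate,
    generate_beat_times,
    synth_ecg,
)
from bandecg.telemetry import resample_uniform


class TestBeatTimes:
    def test_constant_60bpm(self):
        beats = generate_beat_times(SynthConfig(duration=10.0,
                                                hr_profile=ConstantHR(60.0)))
        np.testing.assert_allclose(beats.beat_times, np.arange(10) * 1000.0)

    def test_constant_72bpm_spacing(self):
        beats = generate_beat_times(SynthConfig(duration=60.0,
                                                hr_profile=ConstantHR(72.0)))
        np.testing.assert_allclose(np.diff(beats.beat_times), 60000.0 / 72.0,
                                   atol=1e-9)

    def test_ramp_matches_step_integration_oracle(self):
        dur = 60.0
        cfg = SynthConfig(duration=dur, hr_profile=RampHR(60.0, 120.0, dur))
        beats = generate_beat_times(cfg).beat_times
        assert np.all(np.diff(np.diff(beats)) < 0)  # strictly decreasing spacing
        # independent step-by-step integration of the same profile
        t, expected = 0.0, []
        while t < dur * 1000.0:
            expected.append(t)
            hr = 60.0 + (120.0 - 60.0) * min(t / (dur * 1000.0), 1.0)
            t += 60000.0 / hr
        np.testing.assert_allclose(beats, expected, rtol=1e-12)

    def test_sinusoidal_profile_within_bounds(self):
        cfg = SynthConfig(duration=30.0,
                          hr_profile=SinusoidalHR(80.0, 10.0, 10.0))
        beats = generate_beat_times(cfg).beat_times
        spacing = np.diff(beats)
        assert np.all(spacing > 60000.0 / 91.0) and np.all(spacing < 60000.0 / 69.0)

    def test_profile_leaving_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_beat_times(SynthConfig(duration=10.0,
                                            hr_profile=ConstantHR(10.0)))


class TestSynthEcg:
    def test_r_peak_at_beat_time(self):
        cfg = SynthConfig(duration=4.0, hr_profile=ConstantHR(60.0),
                          baseline_wander_amplitude=0.0, noise_sd=0.0)
        from bandecg.qrs import BeatAnnotations

        sig = synth_ecg(BeatAnnotations(np.array([2000.0]), source="truth"), cfg)
        assert abs(sig.times[np.argmax(sig.values)] - 2000.0) <= 1.0

    def test_zero_amplitude_waves_leave_baseline(self):
        cfg = SynthConfig(duration=5.0, hr_profile=ConstantHR(60.0),
                          noise_sd=0.0)
        cfg.wave_params = {k: (0.0, w, o) for k, (a, w, o) in cfg.wave_params.items()}
        beats = generate_beat_times(cfg)
        sig = synth_ecg(beats, cfg)
        expected = 0.3 * np.sin(2 * np.pi * 0.2 * sig.times / 1000.0)
        np.testing.assert_allclose(sig.values, expected, atol=1e-12)

    def test_seeded_noise_determinism(self):
        cfg = SynthConfig(duration=5.0, hr_profile=ConstantHR(60.0),
                          noise_sd=0.1, seed=42)
        beats = generate_beat_times(cfg)
        a = synth_ecg(beats, cfg).values
        b = synth_ecg(beats, cfg).values
        np.testing.assert_array_equal(a, b)
        cfg2 = SynthConfig(duration=5.0, hr_profile=ConstantHR(60.0),
                           noise_sd=0.1, seed=43)
        assert not np.array_equal(a, synth_ecg(beats, cfg2).values)

    def test_unresolvable_wave_width_rejected(self):
        cfg = SynthConfig(duration=5.0, hr_profile=ConstantHR(60.0))
        beats = generate_beat_times(cfg)
        with pytest.raises(ConfigurationError):
            synth_ecg(beats, cfg, render_rate=100.0)  # R width 6 ms < 2 samples


class TestChannel:
    def _clean_signal(self, duration=20.0):
        cfg = SynthConfig(duration=duration, hr_profile=ConstantHR(72.0),
                          noise_sd=0.0)
        return synth_ecg(generate_beat_times(cfg), cfg)

    def test_no_impairment_identity(self):
        sig = self._clean_signal(20.0)
        stream = channel_emulate(sig, ChannelConfig())
        np.testing.assert_allclose(np.diff(stream.times), 8.0, atol=1e-12)
        assert len(stream) == int(np.floor(20.0 * 125)) + 1

    def test_quantization_error_bounded(self):
        sig = self._clean_signal(10.0)
        ch = ChannelConfig()
        stream = channel_emulate(sig, ch)
        dev_v = np.interp(stream.times, sig.times, sig.values)
        assert np.max(np.abs(stream.values * ch.lsb - dev_v)) <= ch.lsb / 2 + 1e-12

    def test_jittered_timestamps_strictly_increasing(self):
        sig = self._clean_signal(30.0)
        stream = channel_emulate(sig, ChannelConfig(jitter_sd=5.0, seed=3))
        assert np.all(np.diff(stream.times) > 0)

    def test_seeded_determinism(self):
        sig = self._clean_signal(10.0)
        ch = ChannelConfig(jitter_sd=2.0, loss_prob=0.01, seed=9)
        a = channel_emulate(sig, ch)
        b = channel_emulate(sig, ch)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.values, b.values)

    def test_loss_survival_count_within_model_interval(self):
        # Monte-Carlo oracle on the loss model alone: 1000 replicates of the
        # keep-mask give the central 99% interval of surviving-sample counts;
        # the channel's survivor count must fall inside it.
        n = 60 * 125
        loss_prob, burst_mean = 0.01, 5.0
        rng = np.random.default_rng(1234)
        counts = np.array([
            burst_loss_mask(n, loss_prob, burst_mean, rng).sum()
            for _ in range(1000)
        ])
        lo, hi = np.percentile(counts, [0.5, 99.5])
        sig = self._clean_signal(60.0)
        stream = channel_emulate(sig, ChannelConfig(loss_prob=loss_prob,
                                                    burst_length_mean=burst_mean,
                                                    seed=77))
        assert lo <= len(stream) <= hi

    def test_device_rate_above_signal_rate_rejected(self):
        sig = self._clean_signal(5.0)
        with pytest.raises(ConfigurationError):
            channel_emulate(sig, ChannelConfig(device_rate=2000.0))


class TestRoundTrip:
    def test_ground_truth_recovered_without_impairments(self):
        cfg = SynthConfig(duration=60.0, hr_profile=ConstantHR(72.0), noise_sd=0.0)
        truth = generate_beat_times(cfg)
        stream = channel_emulate(synth_ecg(truth, cfg), ChannelConfig())
        detected = detect_qrs(preprocess(resample_uniform(stream)))
        score = score_detection(detected, truth, 20.0)
        assert score.sensitivity == 1.0 and score.positive_predictivity == 1.0
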