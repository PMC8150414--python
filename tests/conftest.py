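import numpy as np
import pytest

from bandecg import (
    ChannelConfig,
    ConstantHR,
    SynthConfig,
    channel_emulate,
    generate_beat_times,
    synth_ecg,
)


def make_clean_record(bpm: float, duration: float = 60.0, seed: int = 1,
                      **channel_kwargs):
    """Ground-truth beats + telemetry stream for a noiseless constant-rate ECG."""
    cfg = SynthConfig(duration=duration, hr_profile=ConstantHR(bpm),
                      noise_sd=0.0, seed=seed)
    beats = generate_beat_times(cfg)
    stream = channel_emulate(synth_ecg(beats, cfg),
                             ChannelConfig(seed=seed, **channel_kwargs))
    return beats, stream


@pytest.fixture(scope="session")
def clean_72() -> tuple:
    """60 s noiseless 72 bpm record through an unimpaired channel."""
    return make_clean_record(72.0)
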