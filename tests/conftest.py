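import numpy as np
import pytest

from imequant.synth.recording import RecordingConfig, UnitSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_recording_config():
    """One clean 10 Hz unit on channel 0, 2 s, no artifacts."""
    return RecordingConfig(
        n_channels=4,
        duration=2.0,
        units=[UnitSpec(channel=0, rate_hz=10.0, amplitude_uv=150.0)],
        noise_sigma=7.5,
        motion_artifact_rate=0.0,
        overrange_artifact_rate=0.0,
        seed=7,
    )
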