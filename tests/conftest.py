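import numpy as np
import pytest

from gaborgist import SynthConfig, VideoVolume, build_default_bank


@pytest.fixture(scope="session")
def default_bank():
    return build_default_bank()


@pytest.fixture(scope="session")
def small_config():
    """Small, fast generator settings used by most synthetic-clip tests."""
    return SynthConfig(frame_size=(48, 64), n_frames=40, blob_radius=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """A 36x40x16 random intensity volume wrapped as a VideoVolume."""
    data = rng.uniform(0.0, 1.0, size=(36, 40, 16))
    return VideoVolume(data=data, frame_rate=25.0, patient_id="p0", clip_id="c0")
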