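import numpy as np
import pytest

from emgnet.signal_io import Recording, WindowSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_window(rng):
    return WindowSample(
        window=rng.normal(size=(8, 52)), gesture_label=2, source=("s0", 0)
    )


@pytest.fixture
def short_recording(rng):
    return Recording(
        signal=rng.normal(size=(8, 104)),
        sample_rate=200.0,
        gesture_label=1,
        subject_id="s0",
    )
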