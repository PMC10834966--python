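import numpy as np
import pytest

from synergait import default_ground_truth, generate_recording


@pytest.fixture(scope="session")
def preset_truth():
    """The packaged four-synergy running preset, 60 cycles, mild noise."""
    return default_ground_truth(seed=7)


@pytest.fixture(scope="session")
def preset_recording(preset_truth):
    """One generated recording shared across read-only tests."""
    return generate_recording(preset_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
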