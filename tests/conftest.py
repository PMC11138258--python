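import numpy as np
import pytest

from eegretest import SimulationSpec, fibonacci_montage


@pytest.fixture(scope="session")
def fast_spec():
    """Reduced study for fast tests: 8 channels, 60 s at 250 Hz."""
    return SimulationSpec(
        n_subjects=6,
        sessions_per_subject=2,
        fs=250.0,
        duration=60.0,
        n_channels=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_montage():
    return fibonacci_montage(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
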