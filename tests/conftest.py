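import numpy as np
import pytest

from racewalk import InertialConfig, SimSpec, ThresholdModel, generate_trial


@pytest.fixture(scope="session")
def cfg() -> InertialConfig:
    return InertialConfig()


@pytest.fixture(scope="session")
def model() -> ThresholdModel:
    return ThresholdModel()


@pytest.fixture(scope="session")
def clean_sim():
    """Noiseless 75 s trial at the default study conditions (~210 steps)."""
    return generate_trial(SimSpec(noise_sd=0.0, duration=75.0))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise trial (SD 0.3 m/s²), seeded."""
    return generate_trial(SimSpec(duration=75.0, seed=42))


def true_threshold(sc):
    """Independent evaluation of the default threshold quadratic."""
    sc = np.asarray(sc, dtype=float)
    return np.maximum(sc**2 / -40.921 + sc / 11.242, 0.0)
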