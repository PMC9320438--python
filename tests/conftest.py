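import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oknkit.detection import StimulusSpec
from oknkit.geometry import derive_calibration
from oknkit.synthetic import SyntheticOKNSpec, generate_okn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib():
    return derive_calibration(0.35, 0.40)


@pytest.fixture(scope="session")
def stimulus_left():
    return StimulusSpec(direction="left", speed_deg_s=20.0)


@pytest.fixture(scope="session")
def clean_fixture():
    """One noise-free 20 s leftward OKN recording with ground truth."""
    spec = SyntheticOKNSpec(seed=1)
    trace, truth = generate_okn(spec)
    return spec, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
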