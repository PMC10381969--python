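import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import calscan as cs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_noiseless():
    """Zero-noise control image at the default acquisition geometry."""
    spec = cs.default_spec("control", noise_scale=0.0)
    img, truth = cs.generate_linescan(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def concordant_noiseless():
    spec = cs.default_spec("concordant_alternans", noise_scale=0.0)
    img, truth = cs.generate_linescan(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
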