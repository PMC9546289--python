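import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_indent_cfg():
    from forcespec.simulate import IndentationSimConfig

    return IndentationSimConfig(noise_sd_pn=0.0, baseline_tilt_range_pn_per_nm=0.0)


@pytest.fixture
def geometry20():
    from forcespec.elasticity import IndenterGeometry

    return IndenterGeometry(face_angle_deg=20.0)
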