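import pytest
from hypothesis import HealthCheck, settings

from preresist import ModelParameters, TumorGeometry

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    """u = 1e-8, l = 1, a = b = d = 0."""
    return ModelParameters()


@pytest.fixture(scope="session")
def geometry_template() -> TumorGeometry:
    """Default conversion constants; set diameters via .with_diameter()."""
    return TumorGeometry(diameter_cm=0.0)
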