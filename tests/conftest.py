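import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulmodens.phantom import PhantomSpec, generate_cohort

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """Five phantom patients at the default geometry (cheap, reused)."""
    cohort, truth = generate_cohort(default_spec.with_(n_patients=5), seed=42)
    return cohort, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
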