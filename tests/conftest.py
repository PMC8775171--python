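import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsedigest.composition import ProximateComposition
from pulsedigest.synthetic import PRESETS, generate_digestion_timecourse

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cp_raw() -> ProximateComposition:
    """Chickpea raw-seed proximate composition (g/100 g, as-is)."""
    return PRESETS["CP"].composition


@pytest.fixture(scope="session")
def cp_starch_noiseless():
    """Noiseless chickpea starch digestion course (truth: Ci 0, Cf 91.67, k 0.018)."""
    return generate_digestion_timecourse("CP", "starch", seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def bb_starch_noiseless():
    """Noiseless black-bean starch course (logistic truth: Cf 100, kmax 1.3, lag 11)."""
    return generate_digestion_timecourse("BB", "starch", seed=0, noise_sd=0.0)


def central_difference(f, x, h=1e-5):
    return (f(x + h) - f(x - h)) / (2.0 * h)
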