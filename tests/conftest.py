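import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_profile():
    """Cosine reference profile fitted on a tight 4-dim ID cluster."""
    from spcdrift import fit_reference

    gen = np.random.default_rng(7)
    X = gen.normal([3.0, 3.0, 3.0, 3.0], 0.5, size=(500, 4))
    return fit_reference(X, "cosine")
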