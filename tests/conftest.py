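import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import histotex as ht

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def masks25():
    return ht.default_masks()


@pytest.fixture(scope="session")
def small_dataset():
    """24-image balanced synthetic dataset (fast shared fixture)."""
    return ht.generate_dataset(ht.GeneratorParams(n_per_class=12, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
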