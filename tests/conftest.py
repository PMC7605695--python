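import numpy as np
import pytest
from hypothesis import settings

from triadscope import GeneratorConfig, generate_study

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_study():
    """Two small classrooms (one rural, one urban) for pipeline-level tests."""
    cfg = GeneratorConfig(
        n_classrooms_rural=1, n_classrooms_urban=1,
        class_sizes_rural=(12,), class_sizes_urban=(14,),
        seed=7,
    )
    return generate_study(cfg)
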