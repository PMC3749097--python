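import numpy as np
import pytest
from hypothesis import settings

from pleurisk import default_cohort_spec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def generation_cohort():
    """One synthetic model-generation cohort (46/49/95), fixed seed."""
    return generate_cohort(default_cohort_spec("generation"), seed=7)


@pytest.fixture(scope="session")
def validation_cohort():
    return generate_cohort(default_cohort_spec("validation"), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
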