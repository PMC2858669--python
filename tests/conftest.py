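import numpy as np
import pytest

from npcharge import (
    GeneratorConfig,
    PropertySpace,
    default_registry,
    generate_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort at seed 1 (the study conditions)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(cohort):
    """Property-space model fitted on the default cohort."""
    return PropertySpace(cohort).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def make_sequence(rng):
    def _make(length=30, alphabet="ACDEFGHIKLMNPQRSTVWY"):
        return random_sequence(rng, length, alphabet)

    return _make
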