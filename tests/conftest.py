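import numpy as np
import pytest

from astigzone.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-eye synthetic cohort with default (realistic-noise) settings."""
    cohort, truth = generate_cohort(GeneratorConfig(n_eyes=25, seed=3))
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Closed-loop cohort: no measurement or refraction noise, SIA scatter 0."""
    config = GeneratorConfig(n_eyes=40, seed=11).noiseless()
    cohort, truth = generate_cohort(config)
    return cohort, truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
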