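import numpy as np
import pytest

from icurecal import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded registry-like cohort, scaled down for fast fits."""
    return generate_cohort(GeneratorConfig(n_patients=6000, seed=11))


@pytest.fixture(scope="session")
def linear_cohort():
    """No unit effects, exactly linear logit miscalibration."""
    return generate_cohort(
        GeneratorConfig(n_patients=10000, sigma_u=0.0, seed=12)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
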