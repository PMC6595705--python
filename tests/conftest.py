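import numpy as np
import pytest

from gepreport.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default-parameter cohort shared across read-only tests."""
    matrix, records = generate_cohort(CohortConfig(n_samples=300, seed=11))
    return matrix, records


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, well-separated cohort: identity and calls are exact."""
    cfg = CohortConfig(n_samples=120, seed=7, noise_sd=1e-6, y_dropout=0.0,
                       cyto_unknown_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
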