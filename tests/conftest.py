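import numpy as np
import pandas as pd
import pytest

import irgpairs as ip


@pytest.fixture(scope="session")
def cohort():
    """Default desk-scale cohort shared by read-only tests."""
    return ip.generate_cohort(ip.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def truth(cohort):
    return ip.truth_report(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Smaller cohort for stages that are quadratic in gene count."""
    spec = ip.CohortSpec(
        n_samples_per_group=80,
        n_genes=500,
        n_de_genes=250,
        n_modules=4,
        module_size=50,
        seed=7,
    )
    return ip.generate_cohort(spec)


@pytest.fixture(scope="session")
def published_model():
    return ip.load_published_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
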