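import numpy as np
import pytest

import vmtopics as v


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared across read-only tests."""
    return v.simulate_cohort(v.GeneratorConfig(n_participants=8, samples_per_participant=10, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return v.fit_lda(small_cohort.counts, K=6, seed=7, n_iterations=400, burn_in=150)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_composition(rng, n):
    x = rng.dirichlet(np.ones(n))
    return x
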