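import numpy as np
import pytest

from plaquetopics import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 60-subject cohort with a planted topic, shared across tests."""
    cfg = SimulationConfig(
        n_subjects=60,
        n_placebo=30,
        n_genera=40,
        k_true=4,
        library_size_median=4000,
        rng_seed=101,
    )
    dataset, truth = simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
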