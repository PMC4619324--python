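import numpy as np
import pytest

from dnamesig import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Discovery-scale cohort with 50 planted probes at delta 0.2."""
    cfg = SimulationConfig(
        n_pos=40, n_neg=40, n_probes=2000, n_informative=50,
        delta=0.2, precision=50.0, seed=101,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted methylation difference (delta = 0)."""
    cfg = SimulationConfig(
        n_pos=40, n_neg=40, n_probes=2000, n_informative=50,
        delta=0.0, precision=50.0, seed=202,
    )
    cohort, _ = simulate_cohort(cfg)
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(7)
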