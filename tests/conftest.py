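import numpy as np
import pytest

from mhbrain.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort with the default planted structure."""
    cfg = SimConfig(n_subjects=1500, seed=42, frac_retest=0.3)
    table, truth = simulate_cohort(cfg, return_truth=True)
    return cfg, table, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted brain-behavior mode (effect_r = 0)."""
    cfg = SimConfig(n_subjects=800, seed=7, effect_r=0.0, frac_retest=0.0)
    table, truth = simulate_cohort(cfg, return_truth=True)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
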