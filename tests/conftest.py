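import numpy as np
import pytest

from mgtlab import CohortDesign, EffectSpec, simulate_lmm_dataset


@pytest.fixture(scope="session")
def reduced_design() -> CohortDesign:
    """Desk-scale cohort: 15 per group, 25 trial types, no dropped runs."""
    return CohortDesign(n_placebo=15, n_probiotics=15, n_dropped_runs=0,
                        n_trial_types=25)


@pytest.fixture(scope="session")
def small_lmm_table(reduced_design):
    """One simulated scored table from the default generative spec."""
    table, truth = simulate_lmm_dataset(EffectSpec(), reduced_design, seed=11)
    return table, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
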