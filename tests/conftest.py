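"""Shared fixtures: small fitted studies reused across test modules."""

import numpy as np
import pytest

from fedyn.fitting import MCMCConfig, sample_posterior
from fedyn.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One 20-mouse group observed weekly to day 90 at low observation noise.

    Low noise keeps fe_max/w_max well identified from day-90 data; the
    default (paper-anchored) noise level is exercised by the four-group
    fixture and the end-to-end checks.
    """
    cfg = SimConfig(
        n_mice_per_group=(20,),
        sacrifice_days=(90,),
        n_rnaseq_per_group=(9,),
        sigma_w=1.0,
        sigma_f=2.0,
        seed=301,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Posterior for the small cohort (2 chains, kept cheap)."""
    cfg, cohort, truth = small_cohort
    draws = sample_posterior(
        cohort, config=MCMCConfig(n_chains=2, n_iter=1000, seed=302)
    )
    return cfg, cohort, truth, draws


@pytest.fixture(scope="session")
def four_group_cohort():
    """Four feeding-duration groups (5 mice each) to day 180."""
    cfg = SimConfig(
        n_mice_per_group=(5, 5, 5, 5),
        sacrifice_days=(30, 60, 90, 180),
        n_rnaseq_per_group=(5, 5, 5, 5),
        seed=303,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def four_group_fit(four_group_cohort):
    cfg, cohort, truth = four_group_cohort
    draws = sample_posterior(
        cohort, config=MCMCConfig(n_chains=2, n_iter=1200, seed=304)
    )
    return cfg, cohort, truth, draws


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
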