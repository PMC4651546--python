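"""Shared fixtures: a small synthetic landscape, a simulated dataset, and a
short fitted posterior reused by the summary/GOF/co-occurrence tests."""

import numpy as np
import pytest

from cooccupancy import (
    MCMCConfig,
    TrueParams,
    generate_landscape,
    run_mcmc,
    scale_covariates,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_landscape():
    grid, raw = generate_landscape(n_rows=5, n_cols=5, seed=7, spatial_smoothness=0.3)
    return grid, raw


@pytest.fixture(scope="session")
def small_covariates(small_landscape):
    grid, raw = small_landscape
    return scale_covariates(raw, grid)


@pytest.fixture(scope="session")
def small_dataset(small_covariates):
    history, latent, detection = simulate_dataset(
        small_covariates, TrueParams(), n_weeks=8, seed=21
    )
    return history, latent, detection


@pytest.fixture(scope="session")
def fitted_samples(small_covariates, small_dataset):
    """A deliberately short fit of the small dataset (shared, read-only)."""
    history, _, _ = small_dataset
    config = MCMCConfig(n_chains=3, n_burn=400, n_iter=400, thin=2, seed=11)
    return run_mcmc(history, small_covariates, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
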