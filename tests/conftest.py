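"""Shared fixtures: synthetic DMS/SHM stand-ins and small simulated GCs."""

import numpy as np
import pytest

from gcresponse import (
    CENTRAL_MIMIC_PARAMS,
    SimConfig,
    TrainConfig,
    default_fixtures,
    fit_model,
    generate_training_set,
    run_simulation,
)


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic synthetic DMS map and 5-mer SHM model (60 nt)."""
    rng = np.random.default_rng(42)
    return default_fixtures(rng)


@pytest.fixture(scope="session")
def amap(fixtures):
    return fixtures[0]


@pytest.fixture(scope="session")
def shm(fixtures):
    return fixtures[1]


@pytest.fixture(scope="session")
def small_config():
    """Fast simulation configuration used by most tree-level tests."""
    return SimConfig(
        carrying_capacity=120,
        time_to_sampling=8.0,
        n_sample=(25, 40),
        initial_population=16,
        death_rate_functional=0.2,
        mutability_multiplier=0.68,
    )


@pytest.fixture(scope="session")
def trained_model(amap, shm):
    """Inference network trained on ~5,000 desk-scale trees (60 nt).

    Shared across the end-to-end tests; this is the expensive fixture of
    the suite (a few minutes on one CPU).
    """
    rng = np.random.default_rng(101)
    ts = generate_training_set(5000, amap, shm, rng)
    return fit_model(ts, train_config=TrainConfig(seed=1))


@pytest.fixture(scope="session")
def small_tree(amap, shm, small_config):
    """One simulated GC genealogy at the fast configuration."""
    rng = np.random.default_rng(3)
    return run_simulation(small_config, CENTRAL_MIMIC_PARAMS, amap, shm, rng)
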