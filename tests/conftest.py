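"""Shared fixtures: cohorts and trained models reused across test modules.

Expensive artifacts (the n=100,000 recovery cohort, trained networks, the
five-seed stability report) are session-scoped so each is built once.
All seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest

import densrisk as dr


@pytest.fixture(scope="session")
def default_config() -> dr.SimulationConfig:
    return dr.SimulationConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config) -> dr.Cohort:
    return dr.generate_cohort(default_config)


@pytest.fixture(scope="session")
def big_cohort() -> dr.Cohort:
    """n=100,000 cohort for parameter-recovery checks."""
    return dr.generate_cohort(dr.SimulationConfig(n_patients=100_000, master_seed=123))


@pytest.fixture(scope="session")
def noiseless_config() -> dr.SimulationConfig:
    return dr.SimulationConfig(dens_noise_sd=0.0, risk_noise_sd=0.0, master_seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config) -> dr.Cohort:
    return dr.generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def default_split(default_cohort):
    return dr.split_cohort(default_cohort, 0.8, seed=0)


@pytest.fixture(scope="session")
def noiseless_split(noiseless_cohort):
    return dr.split_cohort(noiseless_cohort, 0.8, seed=0)


@pytest.fixture(scope="session")
def bif_default(default_split) -> dr.TrainedModel:
    """Bifurcated model trained on the default cohort's training split."""
    train, _ = default_split
    return dr.train_bifurcated(train, dr.NetworkConfig(seed=0))


@pytest.fixture(scope="session")
def bif_noiseless(noiseless_split) -> dr.TrainedModel:
    """Bifurcated model trained on the noiseless cohort (capacity check)."""
    train, _ = noiseless_split
    return dr.train_bifurcated(train, dr.NetworkConfig(seed=0))


@pytest.fixture(scope="session")
def stability_report(default_cohort) -> dr.StabilityReport:
    """Five retrainings differing only in model seed, on one fixed split."""
    return dr.seed_stability(default_cohort, dr.NetworkConfig(), seeds=(0, 1, 2, 3, 4), split_seed=0)


@pytest.fixture(scope="session")
def fresh_eval_cohort() -> dr.Cohort:
    """A large independent cohort for tight error-floor measurement."""
    return dr.generate_cohort(dr.SimulationConfig(n_patients=10_000, master_seed=999))
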