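"""Shared fixtures: synthetic genomes and the expensive end-to-end runs.

The heavyweight computations (default 2-Mb fixture, high-density runs, the
assembly-robustness and power experiments) are session-scoped so every
test that needs them shares one computation.
"""

from __future__ import annotations

import pytest

from crmscan.pipeline import (
    assembly_robustness_experiment,
    fixture_power_check,
    run_hd_protocol,
    train_models,
)
from crmscan.simulate import FixtureConfig, generate_fixture

SMALL_CFG = FixtureConfig(
    genome_length=400_000,
    n_chromosomes=2,
    crms_per_class=20,
    training_per_class=10,
    decoy_count=10,
    seed=7,
)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(SMALL_CFG)


@pytest.fixture(scope="session")
def default_fixture():
    return generate_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def default_models(default_fixture):
    genome, truth = default_fixture
    cls = truth.class_names[0]
    crm_model, bg_model = train_models(genome, truth.exons, truth.training_sets[cls])
    return crm_model, bg_model


@pytest.fixture(scope="session")
def small_models(small_fixture):
    genome, truth = small_fixture
    cls = truth.class_names[0]
    crm_model, bg_model = train_models(genome, truth.exons, truth.training_sets[cls])
    return crm_model, bg_model


@pytest.fixture(scope="session")
def small_hd_run(small_fixture, small_models):
    genome, truth = small_fixture
    crm_model, bg_model = small_models
    return run_hd_protocol(genome, truth.exons, crm_model, bg_model)


@pytest.fixture(scope="session")
def robustness_df():
    """Best-vs-worst fragmentation robustness over six runs (shared)."""
    return assembly_robustness_experiment(base_seed=1, n_runs=6)


@pytest.fixture(scope="session")
def power_result():
    """Full-pipeline power check on the default fixture (shared)."""
    return fixture_power_check(seed=1)
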