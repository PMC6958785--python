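"""Shared fixtures: small seeded synthetic cohorts used across the suite."""

import numpy as np
import pytest

from methdeconv import (
    SimulationConfig,
    make_cohort,
    make_confounder_effects,
    make_reference_profiles,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_profiles():
    """Well-separated 5-type profiles on 1200 probes."""
    return make_reference_profiles(1200, 5, frac_informative=0.2, divergence=0.8, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(60, n_plates=6, seed=12)


@pytest.fixture(scope="session")
def small_effects(small_profiles):
    return make_confounder_effects(
        small_profiles, n_sex_probes=120, n_age_probes=30, n_plates=6,
        effect_scale=0.2, seed=13,
    )


@pytest.fixture(scope="session")
def small_dataset(small_profiles, small_cohort, small_effects):
    """A confounded 1200-probe, 60-sample cohort plus its ground truth."""
    config = SimulationConfig(n_samples=60, n_types=5, alpha0=1.0, epsilon=0.2, seed=14)
    return simulate_dataset(config, small_profiles, small_cohort, small_effects)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, confounder-free 3-type mixture (exactly factorizable)."""
    profiles = make_reference_profiles(300, 3, divergence=1.0, seed=21)
    config = SimulationConfig(n_samples=30, n_types=3, alpha0=1.0, epsilon=0.0, seed=22)
    d, truth = simulate_dataset(config, profiles, None, None)
    return d, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
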