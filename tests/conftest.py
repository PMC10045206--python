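"""Shared fixtures: phantom cohorts and feature tables.

The reference cohort (30 vessels, default study conditions) is
session-scoped because extraction is the expensive step; tests must not
mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcatomics import CVProtocol, PhantomConfig, generate_cohort
from pcatomics.tables import build_feature_table

REFERENCE_SEED = 11


def make_null_config(**overrides) -> PhantomConfig:
    """Config with no class effect: zero mean shift, equal texture scale."""
    params = dict(
        fat_mean_shift_hu=0.0,
        texture_corr_len_pos=0.6,
        texture_corr_len_neg=0.6,
    )
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def reference_cohort():
    config = PhantomConfig(rng_seed=REFERENCE_SEED)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def vessel_table(reference_cohort):
    cohort, labels = reference_cohort
    return build_feature_table(cohort, labels, "Vessel")


@pytest.fixture(scope="session")
def loi_table(reference_cohort):
    cohort, labels = reference_cohort
    return build_feature_table(cohort, labels, "LOI")


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 12-vessel cohort for tests that only need plumbing."""
    config = PhantomConfig(n_vessels=12, slices_per_vessel=10, rng_seed=3)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    cohort, labels = small_cohort
    return build_feature_table(cohort, labels, "Vessel")


@pytest.fixture()
def fast_cv():
    return CVProtocol(n_folds=3, n_repeats=25, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
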