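import dataclasses

import numpy as np
import pytest

from brainstates import pipeline, synth


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete cohort configuration."""
    return synth.GeneratorConfig(
        n_participants=150, seed=11, n_parcels=42, volumes_range=(40, 50)
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synth.generate_cohort(small_config)


@pytest.fixture(scope="session")
def clustered_cohort(small_config):
    """Cohort with fo_high attached via the clustering path."""
    return pipeline.cohort_with_occupancy(
        small_config, use_clustering=True, n_restarts=4
    )


def null_config(**overrides):
    """Generator config with every association switched off."""
    zero_effects = {k: 0.0 for k in synth._default_covariate_effects()}
    base = dict(
        or_per_iqr=1.0,
        tmt_multiplier_per_5pp=1.0,
        covariate_effects=zero_effects,
    )
    base.update(overrides)
    return synth.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
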