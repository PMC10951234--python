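import numpy as np
import pytest

from stresslearn import (
    BackboneConfig,
    CohortSpec,
    cohort_to_dataset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects, 2 groups, 2 weeks: fast enough for every unit test."""
    return generate_cohort(CohortSpec(n_subjects=4, n_groups=2,
                                      days_per_subject=14, seed=3))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return cohort_to_dataset(tiny_cohort)


@pytest.fixture(scope="session")
def small_backbone():
    return BackboneConfig(latent_dim=8, shared_width=16, head_hidden=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
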