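import numpy as np
import pytest

from avakit import ClassifierConfig, CohortSpec, make_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_effect_cohort():
    """8+8 subjects, 30 ROIs, 60 s, rewired propagation between groups."""
    spec = CohortSpec(
        n_per_group=8, n_rois=30, duration_s=60.0, effect_size=0.5, seed=11
    )
    cohort = make_cohort(spec)
    return cohort, list(cohort), list(cohort.labels)


@pytest.fixture()
def fast_cfg():
    return ClassifierConfig(n_splits=8, seed=0)
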