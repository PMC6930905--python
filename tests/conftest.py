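import numpy as np
import pytest

from smnet import CohortConfig, default_effects, default_ground_truth, generate_cohort


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (3 groups x 4 subjects x 2 sessions) for
    pipeline-level tests."""
    return generate_cohort(
        CohortConfig(n_per_group=4, seed=42),
        default_ground_truth(),
        default_effects(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
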