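import numpy as np
import pytest

from rigidlink.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A reduced cohort for fast structural tests (volumes 16^3)."""
    return CohortSpec(
        n_per_group=6,
        volume_shape=(16, 16, 16),
        voxel_size_mm=6.0,
        cluster_center=(10, 6, 10),
        cluster_radius_mm=12.0,
        seed=7,
    )


@pytest.fixture
def study_spec():
    """The default study-scale conditions (22 per group, 32^3 volumes)."""
    return CohortSpec(seed=11)
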