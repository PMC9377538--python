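import numpy as np
import pytest

from wmfnet.cohort import CohortSpec, generate_cohort
from wmfnet.mask import GroupMask


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale cohort: 4 planted WM networks on a 16x16x12 grid."""
    return CohortSpec(
        n_group1=5,
        n_group2=5,
        grid_dims=(16, 16, 12),
        n_volumes=60,
        k_true=4,
        effect_edges=((0, 1),),
        effect_z=0.4,
        n_gm_networks=4,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def full_mask(shape) -> GroupMask:
    """GroupMask covering an entire cuboid."""
    ones = np.ones(shape, dtype=bool)
    return GroupMask(mask=ones, fraction_map=ones.astype(float), threshold=0.5)
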