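import numpy as np
import pytest

from atrophynet import GridSpace, MapKind, SubjectMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space():
    """4x4x4 grid, full mask, identity affine."""
    return GridSpace.full((4, 4, 4))


@pytest.fixture
def masked_space():
    """4x4x4 grid with a 10-voxel mask."""
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask.flat[:10] = True
    return GridSpace(shape=(4, 4, 4), affine=np.eye(4), mask=mask)


def make_map(space, values, kind=MapKind.thickness_mm, subject_id=None):
    return SubjectMap(space=space, values=np.asarray(values, float),
                      kind=kind, subject_id=subject_id)
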