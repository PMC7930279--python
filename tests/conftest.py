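import numpy as np
import pytest

from bwaskit.connectome import VoxelSet
from bwaskit.validation import (
    build_stack,
    null_cohort_config,
    planted_cohort_config,
)


def grid_voxelset(shape, labels=None) -> VoxelSet:
    """All voxels of a small grid, row-major, optionally with atlas labels."""
    n = int(np.prod(shape))
    coords = np.stack(np.unravel_index(np.arange(n), shape), axis=1)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return VoxelSet(np.arange(n), coords, labels, tuple(shape))


# study-condition config factories shared with the validation module
null_config = null_cohort_config
planted_config = planted_cohort_config
cohort_stack = build_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
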