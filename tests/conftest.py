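import numpy as np
import pytest

from mtplus.roi import ConnectomeMatrix
from mtplus.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_human_config():
    return SyntheticConfig.human_like(
        n_subjects=5, n_regions=30, grid_shape=(8, 8, 8), rng_seed=7
    )


@pytest.fixture
def small_macaque_config():
    return SyntheticConfig.macaque_like(
        n_subjects=5, n_regions=30, grid_shape=(8, 8, 8), rng_seed=7
    )


def random_connectome(rng, n=8, labels=None, subject_id="sub-001"):
    """Random symmetric nonnegative matrix with zero diagonal."""
    w = rng.random((n, n))
    w = np.triu(w, 1)
    w = w + w.T
    labels = labels or tuple(f"N{i}" for i in range(n))
    return ConnectomeMatrix(
        w, labels, node_volumes=rng.uniform(0.5, 2.0, n), subject_id=subject_id
    )
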