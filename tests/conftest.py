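import numpy as np
import pytest

from phyloes import DistanceMatrix, decode, random_code


def random_tree(n, seed):
    return decode(random_code(n, np.random.default_rng(seed)))


def euclidean_matrix(n, seed, dim=4):
    """A guaranteed-metric dissimilarity matrix from random points."""
    pts = np.random.default_rng(seed).standard_normal((n, dim))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix.from_array(d)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
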