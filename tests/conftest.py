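import numpy as np
import pytest

from lowbmm.rankcore import RankMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """A hand-checkable 3x4 rank matrix."""
    return RankMatrix(np.array([
        [1, 2, 3, 4],
        [2, 1, 4, 3],
        [4, 3, 2, 1],
    ]))


@pytest.fixture
def random_matrix(rng):
    """20 random rankings of 6 items."""
    return RankMatrix(np.array([rng.permutation(6) + 1 for _ in range(20)]))
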