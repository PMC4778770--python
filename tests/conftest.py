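import numpy as np
import pytest

from commnull.matrix import CommunityMatrix, TraitVector


@pytest.fixture
def rng():
    return np.random.default_rng(20160304)


@pytest.fixture
def checkerboard_2x2():
    return CommunityMatrix(np.array([[1, 0], [0, 1]], dtype=np.uint8))


@pytest.fixture
def small_matrix():
    # 4 species x 5 sites, hand-picked, no empty rows/columns
    occ = np.array([
        [1, 0, 1, 1, 0],
        [0, 1, 1, 0, 1],
        [1, 1, 0, 0, 0],
        [0, 0, 1, 1, 1],
    ], dtype=np.uint8)
    return CommunityMatrix(occ)


@pytest.fixture
def single_site_traits():
    # one site holding three species with traits 1, 2, 4
    matrix = CommunityMatrix(np.ones((3, 1), dtype=np.uint8))
    traits = TraitVector(np.array([1.0, 2.0, 4.0]))
    return matrix, traits


def brute_force_c_score(occ: np.ndarray) -> float:
    """Independent oracle: enumerate checkerboard 2x2 sub-matrices per pair."""
    m, n = occ.shape
    total = 0
    pairs = 0
    for i in range(m - 1):
        for j in range(i + 1, m):
            pairs += 1
            for a in range(n - 1):
                for b in range(a + 1, n):
                    sub = (occ[i, a], occ[i, b], occ[j, a], occ[j, b])
                    if sub in ((1, 0, 0, 1), (0, 1, 1, 0)):
                        total += 1
    return total / pairs
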