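import numpy as np
import pytest

from tensordr import AssociationMatrix, SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_similarity(rng, ids):
    """Random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    n = len(ids)
    g = rng.random((n, n))
    s = np.clip((g + g.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, ids)


@pytest.fixture
def toy_wknn():
    """3 drugs x 2 diseases worked example for neighbour densification.

    Drugs r1, r2 have one association each; r3 is novel.  The drug-drug
    similarity ties r3 to r1 (0.8) and r2 (0.4).
    """
    a = AssociationMatrix(
        np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        ("d1", "d2"),
        ("r1", "r2", "r3"),
    )
    sim = np.array(
        [
            [1.0, 0.5, 0.8],
            [0.5, 1.0, 0.4],
            [0.8, 0.4, 1.0],
        ]
    )
    s = SimilarityMatrix(sim, ("r1", "r2", "r3"))
    return a, s
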