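import numpy as np
import pytest

from copulacci import CountMatrix, SpatialGraph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_matrix():
    """5 spots x 4 genes with hand-set counts; depths are full row sums."""
    counts = np.array(
        [
            [0, 2, 1, 0],
            [3, 0, 0, 1],
            [1, 1, 2, 0],
            [0, 0, 0, 0],
            [5, 2, 1, 3],
        ]
    )
    return CountMatrix(
        spot_ids=[f"s{i}" for i in range(5)],
        gene_ids=["A", "B", "C", "D"],
        counts=counts,
        depths=np.maximum(counts.sum(axis=1), 1),
    )


@pytest.fixture
def path_graph():
    """Directed path 0-1-2 (both directions) with self-loops and labels."""
    edges = [(0, 1), (1, 0), (1, 2), (2, 1), (0, 0), (1, 1), (2, 2)]
    return SpatialGraph(
        3,
        np.array(edges),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        labels=np.array(["c", "c2", "c"]),
    )
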