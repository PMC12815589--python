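import numpy as np
import pytest

from odmc import ContrastPair, CountTable, dunnett_matrix


@pytest.fixture
def two_cluster_table():
    """One group, clusters (3,7) and (7,3): pooled proportions (0.5, 0.5)."""
    return CountTable(
        counts=np.array([[3, 7], [7, 3]]),
        groups=np.array(["g1", "g1"]),
        clusters=np.array(["b1", "b2"]),
        categories=["c1", "c2"],
    )


@pytest.fixture
def two_group_table():
    """Two groups x two clusters x two categories, mild group difference."""
    return CountTable(
        counts=np.array([[4, 6], [6, 4], [2, 8], [3, 7]]),
        groups=np.array(["g1", "g1", "g2", "g2"]),
        clusters=np.array(["b1", "b2", "b1", "b2"]),
        categories=["c1", "c2"],
    )


@pytest.fixture
def simple_pair():
    return ContrastPair(np.array([[-1.0, 1.0]]), np.array([[-1.0, 1.0]]))


@pytest.fixture
def dunnett_pair():
    """Dunnett(C=3) x Dunnett(G=4), the simulation study's contrast set."""
    return ContrastPair(dunnett_matrix(3), dunnett_matrix(4))


def random_count_table(rng, G=3, C=3, B=5, m=30):
    counts = rng.multinomial(m, rng.dirichlet(np.ones(C)), size=G * B)
    groups = np.repeat([f"g{g+1}" for g in range(G)], B)
    clusters = np.array([f"b{i}" for i in range(G * B)])
    return CountTable(
        counts=counts,
        groups=groups,
        clusters=clusters,
        categories=[f"c{j+1}" for j in range(C)],
    )
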