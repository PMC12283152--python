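import numpy as np
import pytest

from spectrumst import CohortConfig, SpanningTree, generate_cohort
from spectrumst.pipeline import score_cohort


def make_path(n: int, labels=None) -> SpanningTree:
    return SpanningTree(n, frozenset((i, i + 1) for i in range(n - 1)),
                        list(labels) if labels else [])


def make_star(n: int, center: int = 0, labels=None) -> SpanningTree:
    edges = frozenset((min(center, i), max(center, i))
                      for i in range(n) if i != center)
    return SpanningTree(n, edges, list(labels) if labels else [])


def random_tree_edges(n: int, rng: np.random.Generator) -> frozenset:
    """Independent random labeled tree (Pruefer decode written for tests)."""
    if n == 2:
        return frozenset({(0, 1)})
    seq = rng.integers(0, n, size=n - 2).tolist()
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    for v in seq:
        leaf = degree.index(1)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[leaf] -= 1
        degree[v] -= 1
    rest = [i for i in range(n) if degree[i] == 1]
    edges.append((rest[0], rest[1]))
    return frozenset(edges)


SMALL_CONFIG = dict(n_rois=20,
                    group_sizes={"motor": 3, "cibi": 5, "bvftd": 3},
                    n_epochs=8, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Matrix-mode cohort small enough for many tests to share."""
    return generate_cohort(CohortConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_cohort(small_cohort)
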