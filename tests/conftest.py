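import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # printed_data importable

from dxlink import builtin_graph, random_cubic_multigraph


@pytest.fixture(scope="session")
def theta():
    return builtin_graph("theta")


@pytest.fixture(scope="session")
def tetrahedron():
    return builtin_graph("tetrahedron")


@pytest.fixture(scope="session")
def cube():
    return builtin_graph("cube")


@pytest.fixture(scope="session")
def random_fixtures():
    """50 seeded cubic multigraphs with at most 9 edges (n in {2, 4, 6})."""
    graphs = []
    for seed in range(50):
        n = (2, 4, 6)[seed % 3]
        graphs.append(random_cubic_multigraph(n, seed))
    return graphs


@pytest.fixture(scope="session")
def loopfree_fixtures(random_fixtures):
    """The loop-free subset, eligible for the truncation machinery."""
    return [g for g in random_fixtures if not g.has_loops()]
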