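import pytest

from mpolyindex import (
    load_partitions,
    load_properties,
    load_published_indices,
    random_chemical_graph,
)


@pytest.fixture(scope="session")
def partitions():
    return load_partitions()


@pytest.fixture(scope="session")
def properties():
    return load_properties()


@pytest.fixture(scope="session")
def published():
    return load_published_indices()


@pytest.fixture
def random_graphs():
    """Factory of seeded random chemical graphs."""

    def make(n_graphs, n_vertices=12, max_degree=4, seed0=0):
        return [
            random_chemical_graph(n_vertices, max_degree, seed0 + k)
            for k in range(n_graphs)
        ]

    return make
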