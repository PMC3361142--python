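import pytest

from ontosim import (
    SimConfig,
    fixture_go_subgraph,
    fixture_toy_dag,
    generate_random_dag,
)


@pytest.fixture(scope="session")
def toy_bundle():
    return fixture_toy_dag()


@pytest.fixture(scope="session")
def subgraph_bundle():
    return fixture_go_subgraph()


@pytest.fixture(scope="session")
def random_dags():
    """A small, seeded family of random DAGs for property checks."""
    return [
        generate_random_dag(SimConfig(n_terms=5 + 3 * i, seed=100 + i))
        for i in range(12)
    ]
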