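import numpy as np
import pytest

from spasne import EmbedConfig, FixtureSpec, generate_fixture, generate_layered_fixture, preprocess


@pytest.fixture(scope="session")
def grid_fixture():
    """Default 4-cluster, 200-cell, 100-gene grid fixture."""
    return generate_fixture()


@pytest.fixture(scope="session")
def grid_processed(grid_fixture):
    return preprocess(grid_fixture.counts).values


@pytest.fixture(scope="session")
def layered_fixture():
    return generate_layered_fixture()


@pytest.fixture(scope="session")
def small_fixture():
    """A fast fixture for optimization-heavy tests."""
    return generate_fixture(
        FixtureSpec(n_clusters=3, cells_per_cluster=15, n_genes=30,
                    n_marker_genes_per_cluster=5, seed=7)
    )


@pytest.fixture
def fast_cfg():
    """Short schedule for tests that exercise the optimizer, not quality."""
    return EmbedConfig(perplexity=10, max_iter=200, momentum_switch_iter=80,
                       exaggeration_iters=80, record_every=40, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
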