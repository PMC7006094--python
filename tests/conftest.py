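import numpy as np
import pytest

import caddkit as ck


@pytest.fixture(scope="session")
def world():
    """Small synthetic study system shared by read-only tests."""
    return ck.build_world(
        seed=7, n_chromosomes=2, chrom_length=30_000, n_genes=8, n_mirnas=4,
        n_sites=300, track_coverage=0.9,
    )


@pytest.fixture(scope="session")
def genome(world):
    return world.genome


@pytest.fixture(scope="session")
def gene_model(world):
    return world.gene_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
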