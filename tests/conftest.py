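import numpy as np
import pytest

import pbclus as pb


@pytest.fixture(scope="session")
def table2():
    """The printed 6-observation worked example."""
    return pb.table2_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric_binary(rng, n, density=0.4, unit_diag=True):
    m = (rng.random((n, n)) < density).astype(int)
    m = ((m + m.T) > 0).astype(int)
    if unit_diag:
        np.fill_diagonal(m, 1)
    return m


def planted_blocks(block_sizes):
    """Block-diagonal binary matrix with identical all-ones columns per block."""
    n = sum(block_sizes)
    m = np.zeros((n, n), dtype=int)
    start = 0
    for size in block_sizes:
        m[start:start + size, start:start + size] = 1
        start += size
    return m
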