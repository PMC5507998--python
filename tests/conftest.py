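import numpy as np
import pytest

from pbsnet import (GrayMatterMask, build_adjacency, local_density,
                    synth_mask)


@pytest.fixture(scope="session")
def line10():
    """Face-adjacent line of 10 voxels along x, with its graph."""
    data = np.zeros((10, 1, 1), dtype=bool)
    data[:] = True
    graph = build_adjacency(GrayMatterMask(data))
    return graph


@pytest.fixture(scope="session")
def block444():
    """Solid 4x4x4 block graph."""
    return build_adjacency(GrayMatterMask(np.ones((4, 4, 4), dtype=bool)))


@pytest.fixture(scope="session")
def block555():
    return build_adjacency(GrayMatterMask(np.ones((5, 5, 5), dtype=bool)))


@pytest.fixture(scope="session")
def small_shell():
    """~1500-voxel shell mask shared across parcellation tests."""
    return synth_mask(1500, rng_seed=7)


@pytest.fixture(scope="session")
def small_shell_graph(small_shell):
    return build_adjacency(small_shell)


def floyd_warshall_oracle(graph):
    """Dense all-pairs shortest paths by plain triple-loop relaxation,
    independent of scipy's graph routines."""
    n = graph.n_voxels
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    adj = graph.adjacency.tocoo()
    for i, j, w in zip(adj.row, adj.col, adj.data):
        d[i, j] = min(d[i, j], w)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d
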