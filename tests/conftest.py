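import numpy as np
import pytest

from connrel.netbuild import ConnectomeMatrix
from connrel.synthgen import TRTConfig, make_template, simulate_trt


def matrix_from_edges(n, edges, labels=None):
    """Build a ConnectomeMatrix from {(i, j): weight} over n nodes."""
    w = np.zeros((n, n))
    for (i, j), val in edges.items():
        w[i, j] = w[j, i] = val
    labels = labels or [chr(ord("A") + k) for k in range(n)]
    return ConnectomeMatrix(labels, w)


def random_weighted_graph(n, density, rng, integer=False):
    """Random symmetric weighted matrix for oracle comparisons."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(len(iu)) < density
    vals = rng.uniform(0.5, 5.0, size=mask.sum())
    if integer:
        vals = np.round(vals) + 1
    w[iu[mask], ju[mask]] = vals
    w += w.T
    return w


@pytest.fixture
def triangle():
    return matrix_from_edges(3, {(0, 1): 1, (0, 2): 1, (1, 2): 1})


@pytest.fixture
def path3():
    return matrix_from_edges(3, {(0, 1): 1, (1, 2): 1})


@pytest.fixture
def star4():
    # hub A with leaves B, C, D
    return matrix_from_edges(4, {(0, 1): 1, (0, 2): 1, (0, 3): 1})


@pytest.fixture
def four_node():
    # strengths (6, 6, 7, 1): the worked hub/rich-club example
    return matrix_from_edges(4, {(0, 1): 3, (0, 2): 3, (1, 2): 3, (2, 3): 1})


@pytest.fixture(scope="session")
def small_template():
    return make_template(20, target_density=0.3, core_fraction=0.2, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_template):
    cfg = TRTConfig(n_subjects=8, sigma_bs2=0.04, sigma_ws2=0.01, seed=7)
    return simulate_trt(small_template, cfg)
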