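import numpy as np
import pytest

from flowgen.fixtures import FixtureConfig, simulate_fixture
from flowgen.maf import MAFLayer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nb_dataset():
    """Small imbalanced negative-binomial dataset shared across tests."""
    return simulate_fixture(FixtureConfig(n_cells=600, n_genes=60, n_types=3,
                                          markers_per_type=5, seed=7))


def make_maf(d, hidden=8, seed=0, randomize=0.0):
    """A MAF layer; ``randomize`` perturbs the conditioner away from the
    identity with Gaussian noise of that scale."""
    layer = MAFLayer(d, hidden, np.random.default_rng(seed))
    if randomize:
        r = np.random.default_rng(seed + 1)
        for p in (layer.W2, layer.b2, layer.b1):
            p.data = p.data + r.normal(0.0, randomize, p.data.shape)
    return layer


def numeric_logdet(forward_vec, x, eps=1e-6):
    """log|det J| of ``forward_vec`` (R^d -> R^d) at ``x`` by central
    finite differences — the independent oracle for analytic logdets."""
    x = np.asarray(x, dtype=np.float64)
    d = x.size
    J = np.zeros((d, d))
    for j in range(d):
        xp, xm = x.copy(), x.copy()
        xp[j] += eps
        xm[j] -= eps
        J[:, j] = (forward_vec(xp) - forward_vec(xm)) / (2 * eps)
    sign, logabs = np.linalg.slogdet(J)
    assert sign != 0, "numerically singular Jacobian"
    return logabs


def two_moons(n, rng, noise=0.1):
    """Seeded 2-D bimodal target for capacity comparisons."""
    t = rng.uniform(0, np.pi, n)
    upper = rng.random(n) < 0.5
    x = np.where(upper, np.cos(t), 1.0 - np.cos(t))
    y = np.where(upper, np.sin(t), 0.5 - np.sin(t))
    return np.column_stack([x, y]) + rng.normal(0.0, noise, (n, 2))
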