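import numpy as np
import pytest

from netforge import Network, generate_er
from netforge.ser import E, initial_state_from_counts, sample_composition, _batch_step, SERParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def er_100_10():
    """The study's standard initial condition: ER graph, N=100, λ=10."""
    return generate_er(100, 10, seed=7)


@pytest.fixture
def path4():
    return Network.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def triangle():
    return Network.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_cliques():
    """Two disjoint 5-cliques."""
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i + 5, j + 5) for i, j in edges]
    return Network.from_edges(10, edges)


def random_small_graph(rng: np.random.Generator, max_n: int = 12) -> Network:
    """Random simple graph with 2..max_n nodes and random edge probability."""
    n = int(rng.integers(2, max_n + 1))
    p = rng.uniform(0.05, 0.9)
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    return Network(adj | adj.T)


def mc_deterministic_counts(net: Network, n_runs: int, t_steps: int,
                            rng: np.random.Generator):
    """Monte-Carlo mean and standard error of per-run co-activation counts.

    Mirrors the deterministic FC protocol's sampling order exactly (same
    composition and arrangement draws), so with a shared seed the mean
    counts agree to machine precision with simulate_deterministic_fc's
    internal average.
    """
    n = net.n_nodes
    states = np.stack([
        initial_state_from_counts(sample_composition(n, rng), rng)
        for _ in range(n_runs)
    ])
    params = SERParams(0.0, 1.0)
    c_runs = np.zeros((n_runs, n, n))
    cur = states
    for t in range(t_steps + 1):
        x = (cur == E).astype(float)
        c_runs += x[:, :, None] * x[:, None, :]
        if t < t_steps:
            cur = _batch_step(net.adj, cur, params, rng)
    mean = c_runs.mean(axis=0)
    se = c_runs.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return mean, se
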