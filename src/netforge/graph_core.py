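"""Graph container, generators, topological overlap and graph-level metrics.

The central similarity measure is the *topological overlap* (TO) between a
pair of nodes i, j of an undirected simple graph with adjacency ``a``::

    to_ij = (sum_k a_ik a_kj + a_ij) / (min(deg_i, deg_j) + 1 - a_ij)

i.e. the number of shared neighbours (counting a direct link as shared),
normalised by the smaller neighbourhood.  TO lies in [0, 1] and is the score
that drives topological-reinforcement rewiring.

Also provided: Erdős–Rényi G(n, M) generation at a prescribed mean degree,
seeded Louvain community detection with Newman–Girvan modularity Q,
degree-preserving (Maslov–Sneppen) randomisation, small-world metrics, and
plain-text graph/matrix I/O.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("netforge")

__all__ = [
    "Network",
    "ModularityResult",
    "generate_er",
    "topological_overlap",
    "modularity_louvain",
    "labels_from_communities",
    "small_world_metrics",
    "maslov_sneppen_rewire",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "write_matrix_csv",
    "read_matrix_csv",
]


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Undirected simple graph over labelled nodes 0..N-1.

    Stored as a dense boolean adjacency matrix (symmetric, zero diagonal),
    which keeps the per-step score computations of the rewiring rules as
    plain matrix algebra.
    """

    adj: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adj)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        a = a.astype(bool)
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adj = a

    # -- basic properties ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1))

    @property
    def mean_degree(self) -> float:
        """Average connectivity λ = 2|E| / N."""
        return 2.0 * self.n_edges / self.n_nodes

    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1).astype(np.int64)

    def copy(self) -> "Network":
        return Network(self.adj.copy())

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "Network":
        a = np.zeros((n_nodes, n_nodes), dtype=bool)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed")
            a[u, v] = a[v, u] = True
        return cls(a)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = sorted(g.nodes())
        if nodes != list(range(len(nodes))):
            g = nx.convert_node_labels_to_integers(g, ordering="sorted")
        return cls(nx.to_numpy_array(g, dtype=bool))

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adj.astype(np.int8))

    def edge_array(self) -> np.ndarray:
        """(M, 2) array of edges with u < v, lexicographically sorted."""
        iu, ju = np.nonzero(np.triu(self.adj, 1))
        return np.column_stack([iu, ju])

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def is_connected(self) -> bool:
        return self.n_components() == 1


@dataclass
class ModularityResult:
    """A partition (affiliation vector) and its Newman–Girvan Q."""

    labels: np.ndarray
    q: float
    communities: list[set[int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_er(n: int, lam: float, seed: int | np.random.Generator | None = None) -> Network:
    """Erdős–Rényi G(n, M) graph at mean degree ``lam``.

    The edge budget is fixed at M = round(lam * n / 2) so that the density
    2M / (n(n-1)) is exactly realised on every draw — the rewiring rules
    conserve this edge budget, and density statements rely on it being exact.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < lam <= n - 1:
        raise ValueError(f"mean degree lam={lam} must be in (0, n-1]")
    m = int(round(lam * n / 2))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    return Network.from_networkx(g)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(net: Network) -> np.ndarray:
    """Pairwise topological overlap matrix, diagonal fixed at 0.

    Isolated nodes get TO = 0 against every partner (the denominator
    min(0, d) + 1 is 1 and the numerator vanishes).
    """
    a = net.adj.astype(np.float64)
    deg = a.sum(axis=1)
    common = a @ a  # common[i, j] = number of shared neighbours
    num = common + a
    den = np.minimum.outer(deg, deg) + 1.0 - a
    to = num / den
    np.fill_diagonal(to, 0.0)
    return to


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------

def labels_from_communities(communities: Sequence[set[int]], n_nodes: int) -> np.ndarray:
    labels = np.empty(n_nodes, dtype=np.int64)
    for k, comm in enumerate(communities):
        for node in comm:
            labels[node] = k
    return labels


def modularity_louvain(net: Network, seed: int | None = None) -> ModularityResult:
    """One stochastic Louvain run (resolution 1) and its Q value.

    Louvain is degenerate on weak-signal graphs: repeated calls with
    different seeds legitimately return different partitions, which the
    consensus machinery exploits.
    """
    if net.n_edges == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    g = net.to_networkx()
    comms = nx.community.louvain_communities(g, seed=seed, resolution=1)
    q = nx.community.modularity(g, comms, resolution=1)
    return ModularityResult(labels_from_communities(comms, net.n_nodes), float(q), [set(c) for c in comms])


# ---------------------------------------------------------------------------
# Null model and small-world metrics
# ---------------------------------------------------------------------------

def maslov_sneppen_rewire(net: Network, seed: int | np.random.Generator | None = None) -> Network:
    """Degree-preserving randomisation: one accepted double-edge swap per link.

    Swaps creating self-loops or multi-edges are rejected.  If the retry
    budget runs out before |E| swaps were accepted (pathological degree
    sequences), the partially randomised graph is returned with a warning.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = net.to_networkx()
    m = net.n_edges
    try:
        nx.double_edge_swap(g, nswap=m, max_tries=100 * m + 100,
                            seed=int(rng.integers(2**31)))
    except nx.NetworkXAlgorithmError:
        warnings.warn("Maslov-Sneppen retry budget exhausted; returning partially rewired graph")
    out = Network.from_networkx(g)
    assert out.n_edges == m
    return out


def small_world_metrics(net: Network, n_null: int = 10,
                        seed: int | np.random.Generator | None = None) -> dict:
    """Clustering C, characteristic path length L, and small-world index.

    The index is the standard ratio (C/C_rand) / (L/L_rand) against
    ``n_null`` Maslov–Sneppen surrogates.  On disconnected graphs L is
    computed on the largest component and the result is flagged.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _c_and_l(network: Network) -> tuple[float, float, bool]:
        g = network.to_networkx()
        c = nx.average_clustering(g)
        connected = nx.is_connected(g)
        if not connected:
            giant = max(nx.connected_components(g), key=len)
            g = g.subgraph(giant)
        l = nx.average_shortest_path_length(g)
        return c, l, connected

    c, l, connected = _c_and_l(net)
    if not connected:
        warnings.warn("graph disconnected; path length computed on largest component")
    null_c, null_l = [], []
    for _ in range(n_null):
        nc, nl, _ = _c_and_l(maslov_sneppen_rewire(net, rng))
        null_c.append(nc)
        null_l.append(nl)
    c_rand, l_rand = float(np.mean(null_c)), float(np.mean(null_l))
    sw = (c / c_rand) / (l / l_rand) if c_rand > 0 and l_rand > 0 else float("nan")
    return {
        "clustering": c,
        "path_length": l,
        "clustering_rand": c_rand,
        "path_length_rand": l_rand,
        "sw_index": sw,
        "connected": connected,
    }


# ---------------------------------------------------------------------------
# I/O — plain-text edge lists, GraphML, headered CSV matrices
# ---------------------------------------------------------------------------

def write_edgelist(net: Network, path: str | Path) -> None:
    """Whitespace-delimited edge list, 0-based node ids, one pair per line.

    A leading comment line carries the node count so isolated trailing nodes
    survive a round-trip.
    """
    with open(path, "w") as fh:
        fh.write(f"# n_nodes {net.n_nodes}\n")
        for u, v in net.edge_array():
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path) -> Network:
    n_nodes = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "n_nodes":
                    n_nodes = int(parts[1])
                continue
            u, v = line.split()[:2]
            edges.append((int(u), int(v)))
    if n_nodes is None:
        n_nodes = max(max(e) for e in edges) + 1 if edges else 0
    return Network.from_edges(n_nodes, edges)


def write_graphml(net: Network, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def read_graphml(path: str | Path) -> Network:
    return Network.from_networkx(nx.read_graphml(path, node_type=int))


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Headered CSV (columns n0..n{N-1})."""
    import pandas as pd

    n = matrix.shape[0]
    pd.DataFrame(matrix, columns=[f"n{i}" for i in range(n)]).to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path).to_numpy()
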