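"""Independent brute-force oracles used by the test suite.

Everything here is written against first principles (explicit loops,
exhaustive enumeration) and deliberately shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

S, E, R = 0, 1, 2


def brute_force_topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TO by explicit neighbourhood-set counting over node pairs."""
    adj = np.asarray(adj, dtype=int)
    n = adj.shape[0]
    neigh = [set(np.flatnonzero(adj[i])) for i in range(n)]
    to = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            common = len(neigh[i] & neigh[j])
            num = common + adj[i, j]
            den = min(len(neigh[i]), len(neigh[j])) + 1 - adj[i, j]
            to[i, j] = num / den
    return to


def ser_step_deterministic(adj: np.ndarray, state: tuple[int, ...]) -> tuple[int, ...]:
    """One synchronous SER update in the deterministic regime (f=0, p=1)."""
    n = len(state)
    out = []
    for i in range(n):
        if state[i] == E:
            out.append(R)
        elif state[i] == R:
            out.append(S)
        else:
            excited_neighbor = any(adj[i, j] and state[j] == E for j in range(n))
            out.append(E if excited_neighbor else S)
    return tuple(out)


def exact_deterministic_coactivation(adj: np.ndarray, t_steps: int) -> np.ndarray:
    """Exact expected co-activation counts under the deterministic protocol.

    The initial distribution is: integer composition (n_e, n_s, n_r) of N
    uniform over the discrete simplex, then a uniform arrangement of states
    over nodes.  Equivalently, every state vector is weighted by
    1 / (n_compositions * n_arrangements(composition)).  All 3^N initial
    states are enumerated and each is evolved deterministically.
    """
    n = adj.shape[0]
    n_compositions = (n + 1) * (n + 2) // 2
    comp_counts: dict[tuple[int, int, int], int] = {}
    all_states = list(itertools.product((S, E, R), repeat=n))
    for st in all_states:
        comp = (st.count(E), st.count(S), st.count(R))
        comp_counts[comp] = comp_counts.get(comp, 0) + 1

    expected = np.zeros((n, n))
    for st in all_states:
        comp = (st.count(E), st.count(S), st.count(R))
        weight = 1.0 / (n_compositions * comp_counts[comp])
        c = np.zeros((n, n))
        cur = st
        for _ in range(t_steps + 1):
            exc = np.array([x == E for x in cur], dtype=float)
            c += np.outer(exc, exc)
            cur = ser_step_deterministic(adj, cur)
        expected += weight * c
    return expected


def normalize_counts(c: np.ndarray) -> np.ndarray:
    """Independent FC normalisation: c_ij / min(c_ii, c_jj), 0 where undefined."""
    n = c.shape[0]
    fc = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = min(c[i, i], c[j, j])
            fc[i, j] = c[i, j] / m if m > 0 else 0.0
    return fc


def two_clique_modularity(k: int) -> float:
    """Closed-form Q of the natural split of two disjoint k-cliques.

    With communities = components, each community holds half the edges and
    half the degree mass: Q = 2 * (1/2 - (1/2)^2) = 1/2.
    """
    m = 2 * (k * (k - 1) // 2)
    within = k * (k - 1) // 2
    deg_sum = k * (k - 1)
    return 2 * (within / m - (deg_sum / (2 * m)) ** 2)


def expected_null_coclassification(labels: np.ndarray) -> float:
    """Chance that two fixed distinct nodes share a module after a uniform
    label shuffle: sum_m s_m (s_m - 1) / (N (N - 1))."""
    labels = np.asarray(labels)
    n = labels.size
    _, sizes = np.unique(labels, return_counts=True)
    return float(np.sum(sizes * (sizes - 1)) / (n * (n - 1)))


def simultaneous_z_threshold(n_comparisons: int, single_level: float = 3.0) -> float:
    """z-bound holding the family-wise confidence of a single ±3 SE check.

    Šidák correction: per-comparison two-sided level alpha_1 = 2 Phi(-3) is
    tightened to 1 - (1 - alpha_1)^(1/m).
    """
    from scipy.stats import norm

    alpha_family = 2 * norm.sf(single_level)
    alpha_per = 1 - (1 - alpha_family) ** (1 / max(n_comparisons, 1))
    return float(norm.isf(alpha_per / 2))
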