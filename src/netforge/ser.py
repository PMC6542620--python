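"""Susceptible–excited–refractory (SER) excitable dynamics on a graph.

Synchronous three-state cellular automaton:

* S → E if at least one neighbour is excited, otherwise with probability f
  (spontaneous activation);
* E → R always;
* R → S with probability p (recovery).

The deterministic regime is f = 0, p = 1; there the dynamics are fully
determined by the initial state.  Functional connectivity (FC) is derived
from the co-activation matrix ``c_ij = Σ_t 1[x_i^t = E] 1[x_j^t = E]``
(summed over all recorded time points, including t = 0) normalised by the
smaller excitation count::

    fc_ij = c_ij / min(c_ii, c_jj)

Two estimation protocols mirror the two regimes: many short runs with
random initial proportions (deterministic), or one long run started from
10% excited nodes (stochastic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Network

__all__ = [
    "S", "E", "R",
    "SERParams",
    "sample_composition",
    "initial_state_from_counts",
    "ser_step",
    "simulate_ser",
    "coactivation",
    "normalize_fc",
    "simulate_deterministic_fc",
    "simulate_stochastic_fc",
]

S, E, R = 0, 1, 2


@dataclass(frozen=True)
class SERParams:
    """Transition probabilities: f spontaneous activation, p recovery."""

    f: float = 0.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")

    @property
    def deterministic(self) -> bool:
        return self.f == 0.0 and self.p == 1.0


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

def sample_composition(n: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Uniform sample of integer counts (n_e, n_s, n_r) with sum n.

    Uniformity over the discrete simplex (stars-and-bars): each of the
    C(n+2, 2) compositions is equally likely, covering the full space of
    state proportions.
    """
    bars = np.sort(rng.choice(n + 2, size=2, replace=False))
    n_e = int(bars[0])
    n_s = int(bars[1] - bars[0] - 1)
    n_r = n - n_e - n_s
    return n_e, n_s, n_r


def initial_state_from_counts(counts: tuple[int, int, int],
                              rng: np.random.Generator) -> np.ndarray:
    """Random arrangement of n_e excited, n_s susceptible, n_r refractory nodes."""
    n_e, n_s, n_r = counts
    state = np.concatenate([
        np.full(n_e, E, dtype=np.int8),
        np.full(n_s, S, dtype=np.int8),
        np.full(n_r, R, dtype=np.int8),
    ])
    return rng.permutation(state)


def _counts_from_proportions(n: int, e: float, s: float, r: float) -> tuple[int, int, int]:
    if not np.isclose(e + s + r, 1.0):
        raise ValueError("proportions must sum to 1")
    n_e = int(round(e * n))
    n_s = int(round(s * n))
    n_s = min(n_s, n - n_e)
    return n_e, n_s, n - n_e - n_s


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def ser_step(net: Network, state: np.ndarray, params: SERParams,
             rng: np.random.Generator) -> np.ndarray:
    """One synchronous update of a single state vector."""
    return _batch_step(net.adj, state[None, :], params, rng)[0]


def _batch_step(adj: np.ndarray, states: np.ndarray, params: SERParams,
                rng: np.random.Generator) -> np.ndarray:
    """Synchronous update of a (runs, N) batch of state vectors.

    All transitions are evaluated against the input states.
    """
    excited = states == E
    driven = (excited @ adj) > 0  # ≥1 excited neighbour
    if params.f > 0:
        spont = rng.random(states.shape) < params.f
        driven = driven | spont
    if params.p < 1:
        recover = rng.random(states.shape) < params.p
    else:
        recover = True
    out = states.copy()
    out[(states == S) & driven] = E
    out[states == E] = R
    out[(states == R) & recover] = S
    return out


def simulate_ser(net: Network, initial: np.ndarray, params: SERParams,
                 t_steps: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Full (t_steps+1, N) state history including the initial state."""
    if t_steps < 0:
        raise ValueError("t_steps must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    hist = np.empty((t_steps + 1, net.n_nodes), dtype=np.int8)
    hist[0] = initial
    for t in range(t_steps):
        hist[t + 1] = _batch_step(net.adj, hist[t][None, :], params, rng)[0]
    return hist


# ---------------------------------------------------------------------------
# Co-activation and FC
# ---------------------------------------------------------------------------

def coactivation(hist: np.ndarray) -> np.ndarray:
    """Joint-excitation counts c_ij over a state history (T, N).

    Diagonal entries are per-node excitation counts; c is symmetric with
    c_ij <= min(c_ii, c_jj).
    """
    hist = np.asarray(hist)
    if hist.size == 0:
        raise ValueError("empty history")
    x = (hist == E).astype(np.float64)
    return x.T @ x


def normalize_fc(c: np.ndarray) -> np.ndarray:
    """FC from co-activation counts: fc_ij = c_ij / min(c_ii, c_jj).

    Pairs involving a never-excited node (zero denominator) get fc = 0,
    so dead nodes never attract links.  The diagonal is set to 0 for use
    as a rewiring score.
    """
    diag = np.diag(c)
    mins = np.minimum.outer(diag, diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mins > 0, c / np.where(mins > 0, mins, 1.0), 0.0)
    np.fill_diagonal(fc, 0.0)
    return fc


def simulate_deterministic_fc(
    net: Network,
    n_runs: int = 5000,
    t_steps: int = 30,
    rng: np.random.Generator | int | None = None,
    proportions: tuple[float, float, float] | None = None,
    average_per_run: bool = False,
) -> np.ndarray:
    """FC under deterministic SER (f=0, p=1) from many short runs.

    Each run draws initial counts (n_e, n_s, n_r) uniformly over the
    discrete simplex (or uses fixed ``proportions`` (e, s, r)), assigns
    states by a random permutation, and simulates ``t_steps`` synchronous
    updates.  Co-activation counts are summed across runs and time
    (including t=0), averaged over runs, then normalised; set
    ``average_per_run`` to normalise each run's counts first and average
    the resulting FC matrices instead.
    """
    if n_runs < 1 or t_steps < 0:
        raise ValueError("need n_runs >= 1 and t_steps >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    params = SERParams(0.0, 1.0)
    n = net.n_nodes

    if proportions is not None:
        counts = _counts_from_proportions(n, *proportions)
        states = np.stack([initial_state_from_counts(counts, rng) for _ in range(n_runs)])
    else:
        states = np.stack([
            initial_state_from_counts(sample_composition(n, rng), rng)
            for _ in range(n_runs)
        ])

    adj = net.adj
    if average_per_run:
        fc_sum = np.zeros((n, n))
        for start in range(0, n_runs, 200):  # chunked: per-run counts are O(runs·N²)
            chunk = states[start:start + 200]
            c_runs = np.zeros((chunk.shape[0], n, n))
            cur = chunk
            for t in range(t_steps + 1):
                x = (cur == E).astype(np.float64)
                c_runs += x[:, :, None] * x[:, None, :]
                if t < t_steps:
                    cur = _batch_step(adj, cur, params, rng)
            fc_sum += sum(normalize_fc(c) for c in c_runs)
        fc = fc_sum / n_runs
        np.fill_diagonal(fc, 0.0)
        return fc

    c = np.zeros((n, n))
    cur = states
    for t in range(t_steps + 1):
        x = (cur == E).astype(np.float64)
        c += x.T @ x  # within-run, same-time joint excitations, summed over runs
        if t < t_steps:
            cur = _batch_step(adj, cur, params, rng)
    return normalize_fc(c / n_runs)


def simulate_stochastic_fc(
    net: Network,
    params: SERParams,
    t_steps: int = 50_000,
    rng: np.random.Generator | int | None = None,
    excited_fraction: float = 0.1,
) -> np.ndarray:
    """FC under stochastic SER from one long run.

    The initial state has round(0.1 N) excited nodes; the remainder is
    split as evenly as possible between S and R (odd remainder: the extra
    node is susceptible), with random assignment to nodes.
    """
    if params.deterministic:
        raise ValueError("f=0, p=1 is the deterministic regime; use simulate_deterministic_fc")
    if t_steps < 1:
        raise ValueError("t_steps must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = net.n_nodes
    n_e = int(round(excited_fraction * n))
    rest = n - n_e
    n_s = rest - rest // 2
    n_r = rest // 2
    state = initial_state_from_counts((n_e, n_s, n_r), rng)
    hist = np.empty((t_steps + 1, n), dtype=np.int8)
    hist[0] = state
    adj = net.adj
    for t in range(t_steps):
        state = _batch_step(adj, state[None, :], params, rng)[0]
        hist[t + 1] = state
    return normalize_fc(coactivation(hist))
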