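"""Module agreement, consensus clustering and null-model statistics.

Community detection on weak-signal graphs is degenerate: repeated Louvain
runs return different partitions.  The agreement (consensus) matrix P turns
that degeneracy into a signal — p_ij is the relative frequency with which
nodes i and j were co-classified across partitions.  Re-running community
detection on P (treated as a weighted graph) yields a representative set of
stable partitions.

Two nulls support significance statements: a size-preserving label shuffle
of each partition (P_null, the chance level of co-classification for given
module sizes), and, at the graph level, Maslov–Sneppen degree-preserving
randomisation (see graph_core).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .graph_core import (
    Network,
    labels_from_communities,
    maslov_sneppen_rewire,
    modularity_louvain,
)

__all__ = [
    "agreement",
    "consensus_partitions",
    "initial_agreement",
    "partition_overlap",
    "matrix_similarity",
    "null_agreement",
    "intramodule_density",
    "ProtoModuleReport",
    "proto_module_analysis",
    "empirical_pvalue",
]


# ---------------------------------------------------------------------------
# Agreement matrices
# ---------------------------------------------------------------------------

def _stack_partitions(partitions: Sequence[np.ndarray]) -> np.ndarray:
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    arr = np.asarray([np.asarray(p) for p in partitions])
    if arr.ndim != 2:
        raise ValueError("partitions have mismatched lengths")
    return arr


def agreement(partitions: Sequence[np.ndarray]) -> np.ndarray:
    """Co-classification frequency matrix P across partitions.

    p_ij = (#partitions with label_i == label_j) / n_partitions; symmetric
    with unit diagonal.
    """
    arr = _stack_partitions(partitions)
    n = arr.shape[1]
    p = np.zeros((n, n))
    for labels in arr:
        p += labels[:, None] == labels[None, :]
    return p / arr.shape[0]


def null_agreement(partitions: Sequence[np.ndarray],
                   seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Agreement after shuffling each partition's node affiliations.

    Module count and sizes are conserved per partition; only which node
    carries which label is randomised.  Gives the chance level of
    co-classification for the observed module-size structure.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _stack_partitions(partitions)
    shuffled = [rng.permutation(labels) for labels in arr]
    return agreement(shuffled)


def consensus_partitions(p: np.ndarray, n: int = 100,
                         seed: int | np.random.Generator | None = None) -> list[np.ndarray]:
    """Representative partitions from weighted Louvain runs on P.

    P is treated as a weighted graph (diagonal zeroed); each run is
    independently seeded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.array(p, dtype=float)
    np.fill_diagonal(w, 0.0)
    if not np.any(w > 0):
        raise ValueError("agreement matrix has no off-diagonal support")
    g = nx.from_numpy_array(w)
    n_nodes = w.shape[0]
    out = []
    for _ in range(n):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31)), resolution=1)
        out.append(labels_from_communities(comms, n_nodes))
    return out


def initial_agreement(net: Network, n_detect: int = 500, n_consensus: int = 100,
                      seed: int | np.random.Generator | None = None
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Consensus description of a graph's own (proto-)modular structure.

    Louvain is applied ``n_detect`` times to the graph, the agreement
    matrix P_init is computed, and ``n_consensus`` weighted Louvain runs on
    P_init give a representative set of stable partitions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = [modularity_louvain(net, seed=int(rng.integers(2**31))).labels
             for _ in range(n_detect)]
    p_init = agreement(parts)
    return p_init, consensus_partitions(p_init, n=n_consensus, seed=rng)


# ---------------------------------------------------------------------------
# Similarity measures
# ---------------------------------------------------------------------------

def partition_overlap(p1: np.ndarray, p2: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalisation) in [0, 1].

    Degenerate conventions: two single-module partitions overlap fully
    (1.0, with a warning); a single-module partition against a nontrivial
    one carries no information (0.0).
    """
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must have equal length")
    t1, t2 = len(np.unique(p1)) == 1, len(np.unique(p2)) == 1
    if t1 and t2:
        warnings.warn("both partitions are single-module; overlap defined as 1.0")
        return 1.0
    if t1 or t2:
        return 0.0
    return float(normalized_mutual_info_score(p1, p2, average_method="arithmetic"))


def matrix_similarity(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation over upper-triangle off-diagonal entries."""
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape:
        raise ValueError("matrices must have equal shapes")
    iu = np.triu_indices(m1.shape[0], k=1)
    x, y = m1[iu], m2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in off-diagonal entries; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def intramodule_density(net: Network, labels: np.ndarray) -> float:
    """Unweighted mean of within-module edge densities.

    Modules with fewer than 2 nodes carry no internal pairs and are
    excluded; an all-singleton partition raises.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != net.n_nodes:
        raise ValueError("partition length does not match the graph")
    densities = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        k = idx.size
        if k < 2:
            continue
        within = net.adj[np.ix_(idx, idx)].sum() / 2
        densities.append(within / (k * (k - 1) / 2))
    if not densities:
        raise ValueError("all modules are singletons; intramodule density undefined")
    return float(np.mean(densities))


def empirical_pvalue(observed: float, null: np.ndarray, alternative: str = "greater") -> float:
    """Permutation p-value with the (b+1)/(n+1) bias-avoiding convention."""
    null = np.asarray(null, float)
    if alternative == "greater":
        b = int(np.sum(null >= observed))
    elif alternative == "less":
        b = int(np.sum(null <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (b + 1) / (null.size + 1)


# ---------------------------------------------------------------------------
# Proto-module pipeline
# ---------------------------------------------------------------------------

@dataclass
class ProtoModuleReport:
    """Outputs of the proto-module amplification analysis.

    Captures (a) structural correspondence of initial and final graphs
    against degree-preserving nulls, (b) the final-run agreement P against
    its shuffle null, with intramodule-density distributions of the initial
    graph under consensus / direct / shuffled partitions, and (c) the
    correspondence between P_init and P.
    """

    p: np.ndarray
    p_init: np.ndarray
    p_null: np.ndarray
    consensus_parts: list[np.ndarray]
    init_consensus_parts: list[np.ndarray]
    # (a) initial vs final graphs
    sim_init_final: np.ndarray = field(default_factory=lambda: np.array([]))
    sim_init_final_null: np.ndarray = field(default_factory=lambda: np.array([]))
    nmi_init_final: np.ndarray = field(default_factory=lambda: np.array([]))
    nmi_init_final_null: np.ndarray = field(default_factory=lambda: np.array([]))
    # (b) intramodule densities of the initial graph
    dens_consensus: np.ndarray = field(default_factory=lambda: np.array([]))
    dens_graph: np.ndarray = field(default_factory=lambda: np.array([]))
    dens_null: np.ndarray = field(default_factory=lambda: np.array([]))
    # (c) P_init vs P
    sim_pinit_p: float = float("nan")
    sim_pinit_p_null: np.ndarray = field(default_factory=lambda: np.array([]))
    nmi_pinit_p: float = float("nan")
    nmi_pinit_p_null: np.ndarray = field(default_factory=lambda: np.array([]))
    pvalues: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def proto_module_analysis(
    net: Network,
    tr_runner: Callable[[Network, int], Network],
    n_runs: int = 500,
    n_detect_init: int = 500,
    n_consensus: int = 100,
    n_null: int = 100,
    n_density_reps: int = 500,
    seed: int | np.random.Generator | None = None,
) -> ProtoModuleReport:
    """Probe whether final modules amplify proto-modules of the initial graph.

    ``tr_runner(net, seed) -> final Network`` abstracts the rewiring engine
    so the same pipeline serves topological reinforcement and the Hebbian
    rule.  The pipeline: ``n_runs`` independent runs from the same initial
    graph, one Louvain partition per final graph, agreement P and its
    consensus partitions; P_init and its consensus partitions from the
    initial graph; statistics against shuffle and degree-preserving nulls
    with empirical (b+1)/(n+1) p-values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags: list[str] = []
    if n_runs < 2:
        flags.append("degenerate: n_runs < 2 gives a 0/1-valued agreement matrix")

    # --- final graphs and their partitions --------------------------------
    finals, final_parts = [], []
    for _ in range(n_runs):
        fin = tr_runner(net, int(rng.integers(2**31)))
        finals.append(fin)
        final_parts.append(modularity_louvain(fin, seed=int(rng.integers(2**31))).labels)
    p = agreement(final_parts)
    cons_parts = consensus_partitions(p, n=n_consensus, seed=rng)

    # --- initial graph consensus ------------------------------------------
    p_init, init_cons_parts = initial_agreement(
        net, n_detect=n_detect_init, n_consensus=n_consensus, seed=rng)

    # --- (a) initial vs final structures, vs degree-preserving null -------
    sim_obs, sim_null, nmi_obs, nmi_null = [], [], [], []
    init_adj = net.adj.astype(float)
    for fin, fpart in zip(finals, final_parts):
        ipart = modularity_louvain(net, seed=int(rng.integers(2**31))).labels
        sim_obs.append(matrix_similarity(init_adj, fin.adj.astype(float)))
        nmi_obs.append(partition_overlap(ipart, fpart))
        surrogate = maslov_sneppen_rewire(net, rng)
        spart = modularity_louvain(surrogate, seed=int(rng.integers(2**31))).labels
        sim_null.append(matrix_similarity(surrogate.adj.astype(float), fin.adj.astype(float)))
        nmi_null.append(partition_overlap(spart, fpart))

    # --- (b) P vs P_null; intramodule densities of the initial graph ------
    p_null = null_agreement(final_parts, seed=rng)

    def _safe_density(labels: np.ndarray) -> float | None:
        try:
            return intramodule_density(net, labels)
        except ValueError:
            return None

    dens_consensus = [_safe_density(cons_parts[int(rng.integers(len(cons_parts)))])
                      for _ in range(n_density_reps)]
    dens_graph, dens_null_list = [], []
    for _ in range(n_density_reps):
        labels = modularity_louvain(net, seed=int(rng.integers(2**31))).labels
        dens_graph.append(_safe_density(labels))
        dens_null_list.append(_safe_density(rng.permutation(labels)))

    def _clean(vals: list) -> np.ndarray:
        return np.array([v for v in vals if v is not None], float)

    # --- (c) P_init vs P ---------------------------------------------------
    sim_pp = matrix_similarity(p_init, p)
    sim_pp_null = np.array([
        matrix_similarity(p_init, null_agreement(final_parts, seed=rng))
        for _ in range(n_null)
    ])
    nmi_pp = float(np.mean([
        partition_overlap(a, b) for a in init_cons_parts for b in cons_parts
    ]))
    null_cons = consensus_partitions(p_null, n=n_consensus, seed=rng)
    nmi_pp_null = np.array([
        partition_overlap(a, b) for a in init_cons_parts for b in null_cons
    ])

    pvals = {
        "sim_init_final": empirical_pvalue(float(np.mean(sim_obs)), np.asarray(sim_null)),
        "nmi_init_final": empirical_pvalue(float(np.mean(nmi_obs)), np.asarray(nmi_null)),
        "sim_pinit_p": empirical_pvalue(sim_pp, sim_pp_null),
        "nmi_pinit_p": empirical_pvalue(nmi_pp, nmi_pp_null),
    }

    return ProtoModuleReport(
        p=p, p_init=p_init, p_null=p_null,
        consensus_parts=cons_parts, init_consensus_parts=init_cons_parts,
        sim_init_final=np.asarray(sim_obs), sim_init_final_null=np.asarray(sim_null),
        nmi_init_final=np.asarray(nmi_obs), nmi_init_final_null=np.asarray(nmi_null),
        dens_consensus=_clean(dens_consensus), dens_graph=_clean(dens_graph),
        dens_null=_clean(dens_null_list),
        sim_pinit_p=sim_pp, sim_pinit_p_null=sim_pp_null,
        nmi_pinit_p=nmi_pp, nmi_pinit_p_null=nmi_pp_null,
        pvalues=pvals, flags=flags,
    )
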