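"""Functional-network analysis: pruning, Markov clustering, topology metrics.

Markov clustering (MCL) simulates random-walk flow on the weighted
association matrix: alternate *expansion* (matrix squaring, which spreads
flow along walks) and *inflation* (elementwise powering + column
renormalization, which sharpens intra-cluster flow) until the flow matrix
stops changing.  Clusters are read off as the attractor systems of the
converged matrix.  Edge weights (combined association scores) are used
directly as flow capacities rather than binarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import FunctionalNetwork

logger = logging.getLogger("bioidnet.network")


@dataclass
class ClusterAssignment:
    """A partition of network nodes into clusters.

    Cluster ids are consecutive from 0, ordered by decreasing cluster size
    with ties broken by the smallest member symbol, so output numbering is
    reproducible across runs and platforms.
    """

    membership: dict[str, int]
    converged: bool = True
    annotations: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(set(self.membership.values()))
        if ids and ids != list(range(len(ids))):
            raise ValueError("cluster ids must be consecutive from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def members(self, cid: int) -> list[str]:
        return sorted(n for n, c in self.membership.items() if c == cid)

    def clusters(self) -> list[list[str]]:
        return [self.members(cid) for cid in range(self.n_clusters)]

    def to_table(self) -> pd.DataFrame:
        rows = [{"node": n, "cluster_id": c} for n, c in self.membership.items()]
        return (
            pd.DataFrame(rows, columns=["node", "cluster_id"])
            .sort_values(["cluster_id", "node"])
            .reset_index(drop=True)
        )


def renumber_clusters(groups: list[list[str]]) -> dict[str, int]:
    """Deterministic ids: decreasing size, ties by smallest member symbol."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {node: cid for cid, group in enumerate(ordered) for node in group}


def prune_unconnected(net: FunctionalNetwork) -> FunctionalNetwork:
    """Remove degree-0 nodes; edges are unchanged."""
    g = net.graph.copy()
    isolated = [n for n, d in g.degree if d == 0]
    g.remove_nodes_from(isolated)
    if isolated:
        logger.info("pruned %d unconnected node(s)", len(isolated))
    return FunctionalNetwork(graph=g)


def _flow_matrix(net: FunctionalNetwork) -> tuple[np.ndarray, list[str]]:
    """Column-stochastic flow matrix with self-loops.

    Self-loop weight is the node's maximum incident edge weight — the
    standard MCL regularization that damps period-2 oscillation.
    """
    a, order = net.adjacency()
    loops = a.max(axis=1)
    loops[loops == 0] = 1.0  # isolated node: unit self-loop keeps columns stochastic
    np.fill_diagonal(a, loops)
    return a / a.sum(axis=0, keepdims=True), order


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0, keepdims=True)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(
    net: FunctionalNetwork,
    inflation: float = 2.0,
    prune_tol: float = 1e-5,
    max_iter: int = 200,
) -> ClusterAssignment:
    """Markov clustering of the weighted network.

    Iterates expansion (M <- M @ M), inflation (M <- M ** inflation,
    columns renormalized) and pruning of entries below ``prune_tol`` until
    the matrix is idempotent within 1e-8 or ``max_iter`` is reached; on
    non-convergence a warning is logged and clusters are read from the
    final matrix with ``converged=False``.

    Attractors are nodes retaining flow on the diagonal; attractor systems
    (diagonal blocks of the converged matrix) define the clusters, and any
    node reached by several systems goes to the one holding more of its
    column mass, ties to the smaller preliminary cluster id.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    m, order = _flow_matrix(net)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < prune_tol] = 0.0
        inflated = _normalize_columns(inflated)
        if np.abs(inflated - m).max() < 1e-8:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    membership = _read_clusters(m, order)
    groups: dict[int, list[str]] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, []).append(node)
    final = renumber_clusters(list(groups.values()))
    logger.info("MCL found %d clusters over %d nodes", len(groups), len(order))
    return ClusterAssignment(membership=final, converged=converged)


def _read_clusters(m: np.ndarray, order: list[str]) -> dict[str, int]:
    """Attractor-system interpretation of a converged MCL matrix."""
    n = len(order)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # fall back: strongest row entry per column
        attractors = sorted(set(int(np.argmax(m[:, j])) for j in range(n)))
    # attractor systems: connected components among attractor rows/columns
    sub = nx.Graph()
    sub.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                sub.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sub)]
    systems.sort(key=lambda s: s[0])  # preliminary ids in node order

    membership: dict[str, int] = {}
    for j in range(n):
        masses = [sum(m[i, j] for i in system) for system in systems]
        best = max(range(len(systems)), key=lambda k: (masses[k], -k))
        membership[order[j]] = best
    return membership


def topology_metrics(net: FunctionalNetwork) -> pd.DataFrame:
    """Per-node degree, average shortest path, and closeness centrality.

    Metrics are hop-based on the unweighted skeleton and computed within
    each node's connected component: average shortest path is the mean hop
    distance to reachable nodes, closeness is (number of reachable nodes) /
    (sum of distances to them).
    """
    g = net.graph
    closeness = nx.closeness_centrality(g, wf_improved=False)
    rows = []
    for node in sorted(g.nodes):
        dists = nx.single_source_shortest_path_length(g, node)
        del dists[node]
        avg = float(np.mean(list(dists.values()))) if dists else 0.0
        rows.append(
            {
                "node": node,
                "degree": g.degree[node],
                "avg_shortest_path": avg,
                "closeness": closeness[node],
            }
        )
    return pd.DataFrame(rows, columns=["node", "degree", "avg_shortest_path", "closeness"])
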