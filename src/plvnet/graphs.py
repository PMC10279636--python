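"""Graph-theory metrics on thresholded connectivity matrices.

Each PLV matrix is proportionally thresholded (default: retain the 20%
strongest connections, weights kept), then summarised by three statistics:

* modularity Q (Louvain maximisation of the weighted Newman formula
  ``Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j)``),
* global efficiency ``E = (1/(n(n-1))) sum_{i!=j} 1/d_ij`` with edge
  length 1/weight and Floyd-Warshall all-pairs shortest paths,
* routing efficiency between two designated node sets (core and extended
  face-network systems): the maximum inverse shortest path length across
  the two sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdedGraph",
    "RoutingMatrix",
    "NodeSetAssignment",
    "PartitionResult",
    "proportional_threshold",
    "shortest_paths",
    "global_efficiency",
    "modularity",
    "modularity_value",
    "routing_matrix",
    "routing_efficiency",
]


@dataclass
class ThresholdedGraph:
    """Weighted undirected graph after proportional thresholding."""

    adjacency: np.ndarray
    density: float
    n_edges: int
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not self.node_labels:
            self.node_labels = [f"node{i}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class RoutingMatrix:
    """Inverse shortest-path-length matrix; unit diagonal by convention."""

    r: np.ndarray
    node_labels: list[str]


@dataclass
class NodeSetAssignment:
    """Parcel membership in the face-processing network's two systems."""

    core: frozenset[str]
    extended: frozenset[str]

    def __post_init__(self) -> None:
        self.core = frozenset(self.core)
        self.extended = frozenset(self.extended)
        if self.core & self.extended:
            raise ValueError("core and extended sets must be disjoint")

    @classmethod
    def from_csv(cls, path) -> "NodeSetAssignment":
        """Read a two-column CSV: parcel_label, system in {core, extended}."""
        import csv

        core, ext = set(), set()
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("parcel_label", "label"):
                    continue
                label, system = row[0].strip(), row[1].strip().lower()
                if system == "core":
                    core.add(label)
                elif system == "extended":
                    ext.add(label)
                else:
                    raise ValueError(f"unknown system {system!r} for {label!r}")
        return cls(core=frozenset(core), extended=frozenset(ext))

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parcel_label", "system"])
            for lbl in sorted(self.core):
                w.writerow([lbl, "core"])
            for lbl in sorted(self.extended):
                w.writerow([lbl, "extended"])


@dataclass
class PartitionResult:
    """Best community partition found and its modularity."""

    q: float
    communities: dict
    n_restarts: int
    seed: int


def _as_matrix(c) -> tuple[np.ndarray, list[str]]:
    if isinstance(c, ConnectivityMatrix):
        return c.plv, list(c.node_labels)
    if isinstance(c, ThresholdedGraph):
        return c.adjacency, list(c.node_labels)
    m = np.asarray(c, dtype=float)
    return m, [f"node{i}" for i in range(m.shape[0])]


def proportional_threshold(c, density: float = 0.20) -> ThresholdedGraph:
    """Retain the strongest fraction of possible connections, weighted.

    Keeps the ``round(density * n(n-1)/2)`` largest off-diagonal weights
    (round-half-up) and zeroes the rest; retained edges keep their weights.
    Ties straddling the cutoff are broken deterministically by lowest node
    index first, with a logged warning.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    mat, labels = _as_matrix(c)
    n = mat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = mat[iu, ju]
    m_possible = n * (n - 1) // 2
    k = int(np.floor(density * m_possible + 0.5))  # round-half-up
    adj = np.zeros_like(mat)
    if k > 0:
        order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
        keep = order[:k]
        if k < m_possible and w[order[k - 1]] == w[order[k]]:
            logger.warning(
                "proportional_threshold: ties at the cutoff weight %.6g; "
                "keeping lowest-index pairs first",
                w[order[k - 1]],
            )
        adj[iu[keep], ju[keep]] = w[keep]
        adj = adj + adj.T
    return ThresholdedGraph(
        adjacency=adj, density=k / m_possible if m_possible else 0.0,
        n_edges=k, node_labels=labels,
    )


def shortest_paths(g: ThresholdedGraph) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1/weight.

    Computed with the Floyd-Warshall algorithm; unreachable pairs are
    +inf and the diagonal is 0.
    """
    adj = g.adjacency
    if adj.min() < 0:
        raise ValueError("negative edge weights are not allowed")
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    d = floyd_warshall(lengths, directed=False, unweighted=False)
    return np.asarray(d)


def global_efficiency(g: ThresholdedGraph) -> float:
    """Average inverse shortest path length over ordered node pairs."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires >= 2 nodes")
    d = shortest_paths(g)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def modularity_value(adjacency: np.ndarray, membership, gamma: float = 1.0) -> float:
    """Direct evaluation of the weighted modularity formula.

    ``Q = (1/2m) sum_ij [A_ij - gamma * k_i k_j / 2m] delta(c_i, c_j)``
    with A the weighted adjacency, k the weighted degrees and m the total
    edge weight.
    """
    a = np.asarray(adjacency, dtype=float)
    member = np.asarray(membership)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise ValueError("graph has no edges")
    same = member[:, None] == member[None, :]
    return float(((a - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def modularity(
    g: ThresholdedGraph,
    gamma: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> PartitionResult:
    """Louvain community detection, best modularity over random restarts.

    The reported ``q`` is the direct evaluation of the weighted modularity
    formula on the returned partition (not the optimizer's internal
    value), so it satisfies the printed definition exactly.
    """
    if g.adjacency.min() < 0:
        raise ValueError("negative edge weights are not allowed")
    if g.n_edges < 1 or g.adjacency.sum() <= 0:
        raise ValueError("modularity requires at least one edge")
    graph = nx.from_numpy_array(g.adjacency)
    rng = np.random.default_rng(seed)
    best_q, best_member = -np.inf, None
    for _ in range(max(int(n_restarts), 1)):
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=gamma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        member = np.empty(g.n_nodes, dtype=int)
        for ci, nodes in enumerate(comms):
            for node in nodes:
                member[node] = ci
        q = modularity_value(g.adjacency, member, gamma)
        if q > best_q:
            best_q, best_member = q, member
    communities = {g.node_labels[i]: int(best_member[i]) for i in range(g.n_nodes)}
    return PartitionResult(
        q=best_q, communities=communities, n_restarts=int(n_restarts), seed=int(seed)
    )


def routing_matrix(g: ThresholdedGraph) -> RoutingMatrix:
    """Inverse shortest-path-length matrix; 0 when unreachable, 1 on the diagonal."""
    d = shortest_paths(g)
    with np.errstate(divide="ignore"):
        r = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(r, 1.0)
    return RoutingMatrix(r=r, node_labels=list(g.node_labels))


def routing_efficiency(r: RoutingMatrix, sets: NodeSetAssignment) -> float:
    """Maximum routing efficiency between the core and extended systems."""
    labels = {lbl: i for i, lbl in enumerate(r.node_labels)}
    core_idx = [labels[x] for x in sets.core if x in labels]
    ext_idx = [labels[x] for x in sets.extended if x in labels]
    if not core_idx or not ext_idx:
        raise ValueError("both node sets must be non-empty within the graph")
    return float(r.r[np.ix_(core_idx, ext_idx)].max())
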