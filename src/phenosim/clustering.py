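"""Mate-bond clusters (the model's species analogue) and disc clusters.

Every organism, its mate and its alternate mate form a cluster seed; seeds
sharing an organism merge until a closed, reproductively isolated set
remains. That fixed point is exactly the set of connected components of the
undirected graph with an edge from each organism to its mate and to its
alternate, which is how clusters are computed here.

Disc clusters treat organisms as discs of radius ``kappa`` (the competition
limit); two discs are connected when their centres are closer than
``2 * kappa``. A bond cluster can span the landscape while no chain of
overlapping discs does — bond percolation without site percolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .reproduction import NO_MATE, MateAssignment, _as_coords


@dataclass(frozen=True)
class BondGraph:
    """Undirected mate/alternate-mate graph over ``n`` organisms."""

    n: int
    edges: np.ndarray  # (m, 2) int array, i < j, deduplicated, no self-loops


@dataclass(frozen=True)
class ClusterPartition:
    """Cluster label per organism plus the number of distinct clusters."""

    labels: np.ndarray
    n_clusters: int


def build_bond_graph(n: int, mates: MateAssignment) -> BondGraph:
    """Edge set {(i, mate[i])} ∪ {(i, alternate[i])}, deduplicated."""
    if n != mates.n:
        raise ValueError("assignment size does not match organism count")
    if n == 0:
        return BondGraph(0, np.empty((0, 2), dtype=np.int64))
    i = np.arange(n)
    parts = [np.column_stack([i, mates.mate])]
    has_alt = mates.alternate != NO_MATE
    if np.any(has_alt):
        parts.append(np.column_stack([i[has_alt], mates.alternate[has_alt]]))
    edges = np.concatenate(parts).astype(np.int64)
    if np.any(edges >= n) or np.any(edges < 0):
        raise ValueError("edge endpoint out of range")
    edges.sort(axis=1)
    edges = np.unique(edges, axis=0)
    edges = edges[edges[:, 0] != edges[:, 1]]
    return BondGraph(n, edges)


def find_clusters(graph: BondGraph) -> ClusterPartition:
    """Connected components of the bond graph.

    Equivalent to the transitive closure of iterative cluster-seed merging:
    both produce the finest partition in which every organism shares a
    cluster with its mate and its alternate.
    """
    if graph.n == 0:
        return ClusterPartition(np.empty(0, dtype=np.int64), 0)
    if len(graph.edges) == 0:
        return ClusterPartition(np.arange(graph.n, dtype=np.int64), graph.n)
    m = coo_matrix(
        (np.ones(len(graph.edges)), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n, graph.n),
    )
    n_comp, labels = connected_components(m, directed=False)
    return ClusterPartition(labels.astype(np.int64), int(n_comp))


def _cluster_extents(coords: np.ndarray, labels: np.ndarray, n_clusters: int):
    minx = np.full(n_clusters, np.inf)
    maxx = np.full(n_clusters, -np.inf)
    miny = np.full(n_clusters, np.inf)
    maxy = np.full(n_clusters, -np.inf)
    np.minimum.at(minx, labels, coords[:, 0])
    np.maximum.at(maxx, labels, coords[:, 0])
    np.minimum.at(miny, labels, coords[:, 1])
    np.maximum.at(maxy, labels, coords[:, 1])
    return minx, maxx, miny, maxy


def spanning_clusters(pop, partition: ClusterPartition, L: float, margin: float) -> set[int]:
    """Labels of clusters reaching within ``margin`` of both opposite boundaries.

    A cluster spans when its extent covers [<= margin, >= L - margin] along
    the x axis or along the y axis. The landscape has no intrinsic length
    scale for "end to end" other than the competition limit, which callers
    normally pass as the margin.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    coords = _as_coords(pop)
    if len(coords) == 0 or partition.n_clusters == 0:
        return set()
    minx, maxx, miny, maxy = _cluster_extents(coords, partition.labels, partition.n_clusters)
    spans = ((minx <= margin) & (maxx >= L - margin)) | (
        (miny <= margin) & (maxy >= L - margin)
    )
    return set(np.flatnonzero(spans).tolist())


def disc_clusters(pop, kappa: float) -> ClusterPartition:
    """Components of the disc-overlap graph: edge iff centre distance < 2*kappa."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    coords = _as_coords(pop)
    n = len(coords)
    if n == 0:
        return ClusterPartition(np.empty(0, dtype=np.int64), 0)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.0 * kappa, output_type="ndarray")
    if len(pairs):
        d2 = np.sum((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2, axis=1)
        pairs = pairs[d2 < (2.0 * kappa) ** 2]
    if len(pairs) == 0:
        return ClusterPartition(np.arange(n, dtype=np.int64), n)
    m = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(m, directed=False)
    return ClusterPartition(labels.astype(np.int64), int(n_comp))


def has_disc_spanning(pop, kappa: float, L: float) -> bool:
    """Whether any chain of overlapping radius-``kappa`` discs spans the space.

    Spanning uses the same extent rule as bond clusters with margin
    ``kappa`` (a disc whose centre is within one radius of the boundary
    touches it).
    """
    coords = _as_coords(pop)
    if len(coords) == 0:
        return False
    partition = disc_clusters(coords, kappa)
    return bool(spanning_clusters(coords, partition, L, margin=kappa))
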