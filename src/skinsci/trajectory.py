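"""Principal-graph pseudotime and ordering diagnostics.

The principal graph is a deliberately light construction: k-means
centroids (default 25 nodes) in aligned-PCA space joined by their
Euclidean minimum spanning tree.  Pseudotime of a cell is the tree
distance from its nearest node to the nearest root node, at node
resolution — no within-edge interpolation, since every downstream check
here is rank-based.  Roots are given as a cell set and mapped to nodes
by nearest assignment (ties to the lowest node index).

Pseudotime is an ordering proxy, not a lineage proof: when an
orthogonal gradient (for example an ambient or state-ratio axis)
dominates variance, the graph follows that gradient instead of the
lineage, which is exactly the failure mode the ordering diagnostics
(rank correlation of pseudotime against an independent per-cell score)
are meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "TrajectoryGraph",
    "PrincipalGraphPseudotime",
    "principal_graph",
    "order_cells",
    "ordering_diagnostics",
]


@dataclass
class TrajectoryGraph:
    node_coords: np.ndarray  # n_nodes x d
    edges: np.ndarray  # n_edges x 2 node indices
    edge_lengths: np.ndarray
    cell_assignment: np.ndarray  # per-cell nearest node
    root_nodes: np.ndarray | None = None
    pseudotime: np.ndarray | None = None  # per cell; inf if unreachable

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def node_distances(self) -> np.ndarray:
        """All-pairs shortest-path distances along the tree."""
        w = sp.csr_matrix(
            (
                np.concatenate([self.edge_lengths, self.edge_lengths]),
                (
                    np.concatenate([self.edges[:, 0], self.edges[:, 1]]),
                    np.concatenate([self.edges[:, 1], self.edges[:, 0]]),
                ),
            ),
            shape=(self.n_nodes, self.n_nodes),
        )
        return shortest_path(w, method="D", directed=False)


class PrincipalGraphPseudotime(BaseEstimator):
    """k-means + minimum-spanning-tree principal graph with rooted pseudotime.

    Parameters
    ----------
    n_nodes : int
        Number of graph nodes (k-means centroids), default 25.
    random_state : int
        Seed for centroid initialization.

    Attributes
    ----------
    graph_ : TrajectoryGraph
    pseudotime_ : ndarray
        Set by :meth:`order_cells`.
    """

    def __init__(self, n_nodes: int = 25, random_state: int = 0):
        self.n_nodes = n_nodes
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not 2 <= self.n_nodes <= X.shape[0]:
            raise ValueError(
                f"n_nodes must lie in [2, n_cells={X.shape[0]}], got {self.n_nodes}"
            )
        km = KMeans(
            n_clusters=self.n_nodes, random_state=self.random_state, n_init=10
        ).fit(X)
        nodes = km.cluster_centers_
        d = cdist(nodes, nodes)
        mst = minimum_spanning_tree(sp.csr_matrix(d)).tocoo()
        edges = np.column_stack([mst.row, mst.col])
        assignment = np.argmin(cdist(X, nodes), axis=1)
        self.graph_ = TrajectoryGraph(
            node_coords=nodes,
            edges=edges,
            edge_lengths=mst.data.copy(),
            cell_assignment=assignment,
        )
        self._X = X
        return self

    def order_cells(self, root_cells) -> np.ndarray:
        """Pseudotime from a nonempty root cell set (indices into fit data).

        Root nodes are the nodes nearest to the root cells; each cell's
        pseudotime is the tree distance from its assigned node to the
        closest root node.  Cells in components disconnected from every
        root get ``inf``.
        """
        root_cells = np.asarray(root_cells)
        if root_cells.size == 0:
            raise ValueError("root_cells must be nonempty")
        if root_cells.max() >= self._X.shape[0] or root_cells.min() < 0:
            raise IndexError("root cell index outside the fitted dataset")
        g = self.graph_
        root_nodes = np.unique(g.cell_assignment[root_cells])
        dist = g.node_distances()
        node_pt = dist[:, root_nodes].min(axis=1)
        self.graph_ = TrajectoryGraph(
            node_coords=g.node_coords,
            edges=g.edges,
            edge_lengths=g.edge_lengths,
            cell_assignment=g.cell_assignment,
            root_nodes=root_nodes,
            pseudotime=node_pt[g.cell_assignment],
        )
        self.pseudotime_ = self.graph_.pseudotime
        return self.pseudotime_


def principal_graph(coords, n_nodes: int = 25, seed: int = 0) -> TrajectoryGraph:
    """Fit an unrooted principal graph (functional wrapper)."""
    return PrincipalGraphPseudotime(n_nodes=n_nodes, random_state=seed).fit(coords).graph_


def order_cells(coords, root_cells, n_nodes: int = 25, seed: int = 0) -> np.ndarray:
    """Fit a principal graph on ``coords`` and return rooted pseudotime."""
    est = PrincipalGraphPseudotime(n_nodes=n_nodes, random_state=seed).fit(coords)
    return est.order_cells(root_cells)


def ordering_diagnostics(pseudotime, score) -> tuple[float, float]:
    """Spearman rho and Kendall tau of pseudotime against a per-cell score.

    Non-finite pseudotime values are excluded pairwise; fewer than three
    finite pairs is an error.
    """
    pt = np.asarray(pseudotime, dtype=float)
    sc = np.asarray(score, dtype=float)
    if pt.shape != sc.shape:
        raise ValueError("pseudotime and score must be aligned per cell")
    ok = np.isfinite(pt) & np.isfinite(sc)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite (pseudotime, score) pairs")
    rho = scipy.stats.spearmanr(pt[ok], sc[ok]).statistic
    tau = scipy.stats.kendalltau(pt[ok], sc[ok]).statistic
    return float(rho), float(tau)
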