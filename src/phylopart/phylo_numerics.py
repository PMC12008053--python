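"""Matrix representations of a phylogeny.

All downstream statistics consume one of four objects derived from the
tree: patristic tip-to-tip distances, the Brownian-motion covariance V
(V_ij = depth of the tips' most recent common ancestor), the Abouheif
proximity matrix, and a principal-coordinate (PCoA) eigenbasis of the
patristic distances.  Tip order everywhere is the tree's leaf-iteration
order, as returned by :func:`phylopart.io_model.tip_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io_model import tip_labels


def _leaves(tree: dendropy.Tree) -> list[dendropy.Node]:
    return list(tree.leaf_node_iter())


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance from the root to each node (root depth 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def patristic_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix (Myr x 2), with tip labels.

    Uses dendropy's phylogenetic distance matrix; zero diagonal, symmetric.
    """
    leaves = _leaves(tree)
    if len(leaves) < 2:
        raise ValueError("patristic matrix needs >= 2 tips")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                leaves[i].taxon, leaves[j].taxon
            )
    return d, tip_labels(tree)


def bm_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance V: V_ij = root-to-MRCA depth, V_ii = tip depth.

    Computed by a single post-order traversal (independently of the
    patristic matrix): at each internal node, every pair of tips drawn from
    two different child subtrees has that node as its MRCA.
    """
    leaves = _leaves(tree)
    if len(leaves) < 2:
        raise ValueError("BM covariance needs >= 2 tips")
    n = len(leaves)
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    depths = _node_depths(tree)

    V = np.zeros((n, n))
    subtree: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node]
            V[i, i] = depths[node]
            subtree[node] = np.array([i], dtype=np.intp)
            continue
        child_sets = [subtree.pop(ch) for ch in node.child_nodes()]
        h = depths[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ii = child_sets[a][:, None]
                jj = child_sets[b][None, :]
                V[ii, jj] = h
                V[jj.T, ii.T] = h
        subtree[node] = np.concatenate(child_sets)
    return V, tip_labels(tree)


def abouheif_proximity(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Abouheif proximity A: A_ij = prod over internal nodes on the i-j path
    (the MRCA plus every internal node strictly between the MRCA and each
    tip) of 1/(number of direct descendants); zero diagonal.

    Polytomies contribute the actual child count (1/3 for a trichotomy).
    """
    leaves = _leaves(tree)
    if len(leaves) < 2:
        raise ValueError("Abouheif proximity needs >= 2 tips")
    n = len(leaves)
    n_child = {
        node: len(node.child_nodes())
        for node in tree.preorder_internal_node_iter()
    }
    # ancestor chain per tip, nearest first
    chains: list[list[dendropy.Node]] = []
    for leaf in leaves:
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains.append(chain)
    positions = [{node: k for k, node in enumerate(chain)} for chain in chains]

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pos_j = positions[j]
            for ki, node in enumerate(chains[i]):
                if node in pos_j:
                    mrca, kj = node, pos_j[node]
                    break
            path_nodes = chains[i][:ki] + chains[j][:kj] + [mrca]
            w = 1.0
            for node in path_nodes:
                w /= n_child[node]
            A[i, j] = A[j, i] = w
    return A, tip_labels(tree)


@dataclass
class PCoABasis:
    """Principal-coordinate basis of a distance matrix.

    ``axes`` has one column per retained positive eigenvalue, scaled so
    each column's squared norm equals its eigenvalue (classical scaling).
    """

    eigenvalues: np.ndarray
    axes: np.ndarray
    tip_order: list[str]
    n_discarded: int

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]


def pcoa(
    dist: np.ndarray,
    tip_order: list[str] | None = None,
    rel_tol: float = 1e-10,
) -> PCoABasis:
    """Classical PCoA by Gower double-centering and eigendecomposition.

    Axes with eigenvalue <= ``rel_tol`` x the largest eigenvalue are
    discarded (patristic matrices need not be Euclidean-embeddable); the
    discarded count is recorded.  Each axis is sign-flipped so its
    largest-magnitude entry is positive, for backend-independent output.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (d ** 2) @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = rel_tol * max(vals[0], 0.0)
    keep = vals > tol
    if not keep.any():
        raise ValueError("degenerate distances: no positive PCoA eigenvalue")
    kept_vals = vals[keep]
    axes = vecs[:, keep] * np.sqrt(kept_vals)
    for k in range(axes.shape[1]):
        if axes[np.argmax(np.abs(axes[:, k])), k] < 0:
            axes[:, k] = -axes[:, k]
    return PCoABasis(
        eigenvalues=kept_vals,
        axes=axes,
        tip_order=list(tip_order) if tip_order is not None else [],
        n_discarded=int(n - keep.sum()),
    )


@dataclass
class NodeInfo:
    """Per-node divergence ages and clade sizes.

    ``age`` is the maximum path length from the node down to any of its
    descendant tips (on an ultrametric tree, the common value);
    ``tip_count`` the number of descendant tips.  ``ultrametric_deviation``
    is the spread (max - min) of root-to-tip depths.
    """

    age: dict[dendropy.Node, float]
    tip_count: dict[dendropy.Node, int]
    ultrametric_deviation: float


def node_ages_and_sizes(tree: dendropy.Tree) -> NodeInfo:
    """Compute divergence age and descendant-tip count for every node."""
    age: dict[dendropy.Node, float] = {}
    count: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            age[node] = 0.0
            count[node] = 1
        else:
            age[node] = max(
                age[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes()
            )
            count[node] = sum(count[ch] for ch in node.child_nodes())
    depths = _node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    return NodeInfo(
        age=age,
        tip_count=count,
        ultrametric_deviation=float(max(tip_depths) - min(tip_depths)),
    )
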