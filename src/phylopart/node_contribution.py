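"""Analysis-of-traits node statistics along a phylogeny.

Each internal node's divergence is summarized by the spread of its
daughter-clade trait means: the divergence size D, a contribution index
CI giving the node's share of tree-wide trait variation, and a
tip-shuffling p-value for D.  Node means are unweighted recursive
averages of daughter means (each daughter counts once regardless of its
size), which removes sampling-imbalance bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_model import tip_labels
from .phylo_numerics import node_ages_and_sizes


def recursive_node_means(
    tree: dendropy.Tree, x: np.ndarray, weighted: bool = False
) -> dict[dendropy.Node, np.ndarray]:
    """Per-node trait mean(s) by post-order recursion.

    ``x`` is aligned to tip order and may be 1-D (one trait vector) or
    2-D with shape (n_tips, m) for m vectors at once (used by the
    permutation test).  With ``weighted=True`` daughters are averaged
    with tip-count weights instead of equally (sensitivity option).
    """
    x = np.asarray(x, dtype=float)
    vec = np.atleast_2d(x.T).T  # (n_tips, m)
    leaves = list(tree.leaf_node_iter())
    if vec.shape[0] != len(leaves):
        raise ValueError("trait length does not match tip count")
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    counts = None
    if weighted:
        counts = node_ages_and_sizes(tree).tip_count
    means: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            means[node] = vec[idx[node]]
        else:
            kids = node.child_nodes()
            stack = np.vstack([means[ch] for ch in kids])
            if weighted:
                w = np.array([counts[ch] for ch in kids], dtype=float)
                means[node] = (w[:, None] * stack).sum(axis=0) / w.sum()
            else:
                means[node] = stack.mean(axis=0)
    if x.ndim == 1:
        return {nd: m[0] for nd, m in means.items()}
    return means


def divergence_size(
    node: dendropy.Node, means: dict[dendropy.Node, np.ndarray]
) -> np.ndarray | float:
    """D at a node: |difference of daughter means| for a binary node,
    sample SD of daughter means at a polytomy."""
    kids = node.child_nodes()
    if len(kids) < 2:
        raise ValueError("divergence size needs an internal node")
    stack = np.vstack([np.atleast_1d(means[ch]) for ch in kids])
    if len(kids) == 2:
        d = np.abs(stack[0] - stack[1])
    else:
        d = np.std(stack, axis=0, ddof=1)
    return float(d[0]) if d.size == 1 else d


def contribution_index(
    tree: dendropy.Tree, x: np.ndarray, weighting: str = "tips"
) -> dict[dendropy.Node, float]:
    """Per-node contribution index, normalized over internal nodes.

    SS_k = sum over daughters d of (mean(d) - mean(k))^2; the node score
    is n_k * SS_k with ``weighting='tips'`` (n_k = descendant tip count,
    the default: deep divergences affecting many species weigh more) or
    SS_k alone with ``weighting='none'``; CI_k = score_k / sum of scores.
    """
    if weighting not in ("tips", "none"):
        raise ValueError("weighting must be 'tips' or 'none'")
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("no tree-wide variation: constant trait")
    means = recursive_node_means(tree, x)
    info = node_ages_and_sizes(tree)
    scores: dict[dendropy.Node, float] = {}
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        ss = sum((means[ch] - means[node]) ** 2 for ch in kids)
        w = info.tip_count[node] if weighting == "tips" else 1.0
        scores[node] = w * ss
    total = sum(scores.values())
    if total == 0:
        raise ValueError("no tree-wide variation: all divergences zero")
    return {nd: s / total for nd, s in scores.items()}


def divergence_pvalue(
    tree: dendropy.Tree,
    x: np.ndarray,
    node: dendropy.Node,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Tip-shuffling p-value for one node's divergence size (one-sided)."""
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    x = np.asarray(x, dtype=float)
    means = recursive_node_means(tree, x)
    d_obs = divergence_size(node, {k: np.atleast_1d(v) for k, v in means.items()})
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
    pmeans = recursive_node_means(tree, perms)
    d_perm = divergence_size(node, pmeans)
    return (int(np.sum(d_perm >= d_obs)) + 1) / (n_perm + 1)


def _clade_summary(node: dendropy.Node, max_names: int = 3) -> str:
    parts = []
    for ch in node.child_nodes():
        tips = ([ch] if ch.is_leaf() else list(ch.leaf_iter()))
        names = [t.taxon.label for t in tips[:max_names]]
        extra = len(tips) - len(names)
        s = ", ".join(names) + (f", +{extra}" if extra > 0 else "")
        parts.append(s)
    return " vs. ".join(parts)


@dataclass
class NodeContributionTable:
    """Ranked per-node report (CI, D, p, n, age, daughter summaries)."""

    table: pd.DataFrame
    n_permutations: int
    seed: int
    weighting: str


def aot_report(
    tree: dendropy.Tree,
    x: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    ci_floor: float = 0.005,
    weighting: str = "tips",
) -> NodeContributionTable:
    """Ranked table of internal-node divergences with CI above a floor.

    All nodes share one set of tip permutations, so the report costs one
    vectorized traversal per permutation regardless of tree size.
    """
    x = np.asarray(x, dtype=float)
    ci = contribution_index(tree, x, weighting=weighting)
    means = recursive_node_means(tree, x)
    means1 = {k: np.atleast_1d(v) for k, v in means.items()}
    info = node_ages_and_sizes(tree)

    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
    pmeans = recursive_node_means(tree, perms)

    rows = []
    for node in tree.preorder_internal_node_iter():
        if ci[node] <= ci_floor:
            continue
        d_obs = divergence_size(node, means1)
        d_obs = float(np.atleast_1d(d_obs)[0])
        d_perm = np.atleast_1d(divergence_size(node, pmeans))
        p = (int(np.sum(d_perm >= d_obs)) + 1) / (n_perm + 1)
        rows.append(
            {
                "ci": ci[node],
                "d": d_obs,
                "p": p,
                "n": info.tip_count[node],
                "age": info.age[node],
                "clades": _clade_summary(node),
            }
        )
    table = pd.DataFrame(rows).sort_values("ci", ascending=False, kind="stable")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return NodeContributionTable(
        table=table.reset_index(drop=True),
        n_permutations=n_perm,
        seed=seed,
        weighting=weighting,
    )
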