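"""Distance-based tree building, rooting and tree comparison.

Three agglomerative builders share one deterministic core:

* ``upgma_tree`` — unweighted pair-group average linkage; assumes a
  molecular clock and returns a rooted ultrametric tree.
* ``nj_tree`` — Saitou–Nei neighbor joining (Q-criterion pair selection,
  standard branch-length formulas); returns an unrooted tree and is
  exact on additive matrices.
* ``bionj_tree`` — neighbor joining with BIONJ's variance-weighted
  matrix reduction: the reduced distance to a new node is a convex
  combination of the two joined rows with weight lambda chosen to
  minimize the variance of the reduced matrix (clamped to [0, 1]).
  On noise-free additive input it coincides with NJ.

Ties in the agglomeration criterion are broken by the lexicographically
smallest pair of cluster representative labels, so identical inputs give
byte-identical Newick output. Negative NJ/BIONJ branch-length estimates
are clamped to zero with the deficit transferred to the sibling edge.

Trees are :class:`skbio.TreeNode` objects; Robinson–Foulds comparison and
Newick serialization delegate to scikit-bio.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .matrix import LabeledMatrix

logger = logging.getLogger(__name__)

PhyloTree = TreeNode

TREE_METHODS = ("upgma", "nj", "bionj")


def _leaf(label: str) -> TreeNode:
    return TreeNode(name=label)


def _closest_pair(dist: dict, reps: dict, keys: list, scores: dict) -> tuple:
    """Pair of active keys minimizing ``scores``; ties broken by the
    lexicographically smallest sorted pair of representative labels.

    Ties are detected with a relative tolerance: analytically equal
    scores (e.g. the complementary Q-criterion pairs of a 4-node stage)
    differ by rounding noise, and resolving them lexicographically keeps
    the output invariant under rescaling of the input matrix.
    """
    best = None
    best_score = None
    best_reps = None
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            s = scores[frozenset((a, b))]
            pair_reps = tuple(sorted((reps[a], reps[b])))
            if best is None:
                best, best_score, best_reps = (a, b), s, pair_reps
                continue
            tol = 1e-9 * (1.0 + abs(best_score))
            if s < best_score - tol:
                best, best_score, best_reps = (a, b), s, pair_reps
            elif s <= best_score + tol and pair_reps < best_reps:
                best, best_score, best_reps = (a, b), min(s, best_score), pair_reps
    return best


def _check_matrix(matrix: LabeledMatrix, min_labels: int, op: str) -> None:
    if len(matrix) < min_labels:
        raise ValueError(f"{op} needs at least {min_labels} labels, got {len(matrix)}")


def upgma_tree(matrix: LabeledMatrix) -> TreeNode:
    """Rooted ultrametric tree by average-linkage agglomeration.

    The closest pair of clusters is merged at height d/2; distances to the
    merged cluster are the size-weighted average of the members' distances,
    so every leaf ends at the same root-to-leaf depth.
    """
    _check_matrix(matrix, 2, "UPGMA")
    labels = matrix.labels
    nodes = {i: _leaf(l) for i, l in enumerate(labels)}
    reps = {i: l for i, l in enumerate(labels)}
    sizes = {i: 1 for i in nodes}
    heights = {i: 0.0 for i in nodes}
    dist = {
        frozenset((i, j)): float(matrix.values[i, j])
        for i in nodes
        for j in nodes
        if i < j
    }
    next_id = len(labels)
    while len(nodes) > 1:
        keys = sorted(nodes)
        a, b = _closest_pair(dist, reps, keys, dist)
        d_ab = dist[frozenset((a, b))]
        height = d_ab / 2.0
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = height - heights[a]
        child_b.length = height - heights[b]
        # children ordered by representative label for stable output
        if reps[b] < reps[a]:
            child_a, child_b = child_b, child_a
        parent = TreeNode(children=[child_a, child_b])
        u = next_id
        next_id += 1
        for k in keys:
            if k in (a, b):
                continue
            d_new = (
                sizes[a] * dist[frozenset((a, k))]
                + sizes[b] * dist[frozenset((b, k))]
            ) / (sizes[a] + sizes[b])
            dist[frozenset((u, k))] = d_new
        for k in keys:
            dist.pop(frozenset((a, k)), None)
            dist.pop(frozenset((b, k)), None)
        nodes.pop(a), nodes.pop(b)
        nodes[u] = parent
        reps[u] = min(reps.pop(a), reps.pop(b))
        sizes[u] = sizes.pop(a) + sizes.pop(b)
        heights[u] = height
    root = nodes.popitem()[1]
    root.length = None
    return root


def _clamp_pair(b_i: float, b_j: float) -> tuple[float, float]:
    """Clamp negative branch estimates to 0, moving the deficit to the
    sibling so the pair's summed length is preserved."""
    if b_i < 0:
        logger.debug("clamping negative branch length %.3g", b_i)
        b_j += b_i
        b_i = 0.0
    if b_j < 0:
        logger.debug("clamping negative branch length %.3g", b_j)
        b_i += b_j
        b_j = 0.0
    return max(b_i, 0.0), max(b_j, 0.0)


def _nj_like(matrix: LabeledMatrix, use_bionj: bool) -> TreeNode:
    _check_matrix(matrix, 3, "BIONJ" if use_bionj else "NJ")
    labels = matrix.labels
    nodes = {i: _leaf(l) for i, l in enumerate(labels)}
    reps = {i: l for i, l in enumerate(labels)}
    dist = {
        frozenset((i, j)): float(matrix.values[i, j])
        for i in nodes
        for j in nodes
        if i < j
    }
    var = dict(dist)  # BIONJ initializes variances to the distances
    next_id = len(labels)

    while len(nodes) > 3:
        keys = sorted(nodes)
        r = len(keys)
        row_sum = {
            i: sum(dist[frozenset((i, k))] for k in keys if k != i) for i in keys
        }
        q = {
            frozenset((i, j)): (r - 2) * dist[frozenset((i, j))]
            - row_sum[i]
            - row_sum[j]
            for n_, i in enumerate(keys)
            for j in keys[n_ + 1 :]
        }
        a, b = _closest_pair(dist, reps, keys, q)
        d_ab = dist[frozenset((a, b))]
        b_a = 0.5 * d_ab + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        b_b = d_ab - b_a

        if use_bionj:
            v_ab = var[frozenset((a, b))]
            if v_ab > 0:
                lam = 0.5 + sum(
                    var[frozenset((b, k))] - var[frozenset((a, k))]
                    for k in keys
                    if k not in (a, b)
                ) / (2.0 * (r - 2) * v_ab)
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
        else:
            lam = 0.5

        child_a, child_b = nodes[a], nodes[b]
        child_a.length, child_b.length = _clamp_pair(b_a, b_b)
        if reps[b] < reps[a]:
            child_a, child_b = child_b, child_a
        parent = TreeNode(children=[child_a, child_b])
        u = next_id
        next_id += 1
        for k in keys:
            if k in (a, b):
                continue
            d_ak = dist[frozenset((a, k))]
            d_bk = dist[frozenset((b, k))]
            if use_bionj:
                # variance-weighted reduction; b_a/b_b are the raw estimates
                d_new = lam * (d_ak - b_a) + (1.0 - lam) * (d_bk - b_b)
                v_new = (
                    lam * var[frozenset((a, k))]
                    + (1.0 - lam) * var[frozenset((b, k))]
                    - lam * (1.0 - lam) * v_ab
                )
                var[frozenset((u, k))] = v_new
            else:
                d_new = 0.5 * (d_ak + d_bk - d_ab)
            dist[frozenset((u, k))] = d_new
        for k in keys:
            dist.pop(frozenset((a, k)), None)
            dist.pop(frozenset((b, k)), None)
            var.pop(frozenset((a, k)), None)
            var.pop(frozenset((b, k)), None)
        nodes.pop(a), nodes.pop(b)
        nodes[u] = parent
        reps[u] = min(reps.pop(a), reps.pop(b))

    # resolve the final three subtrees around an unrooted central node
    x, y, z = sorted(nodes)
    d_xy = dist[frozenset((x, y))]
    d_xz = dist[frozenset((x, z))]
    d_yz = dist[frozenset((y, z))]
    for key, b in (
        (x, 0.5 * (d_xy + d_xz - d_yz)),
        (y, 0.5 * (d_xy + d_yz - d_xz)),
        (z, 0.5 * (d_xz + d_yz - d_xy)),
    ):
        node = nodes[key]
        node.length = max(b, 0.0)
        if b < 0:
            logger.debug("clamping negative terminal branch %.3g", b)
    ordered = sorted((x, y, z), key=lambda key: reps[key])
    root = TreeNode(children=[nodes[key] for key in ordered])
    return root


def nj_tree(matrix: LabeledMatrix) -> TreeNode:
    """Unrooted tree by Saitou–Nei neighbor joining."""
    return _nj_like(matrix, use_bionj=False)


def bionj_tree(matrix: LabeledMatrix) -> TreeNode:
    """Unrooted tree by BIONJ (variance-weighted neighbor joining)."""
    return _nj_like(matrix, use_bionj=True)


def build_tree(matrix: LabeledMatrix, method: str = "bionj") -> TreeNode:
    """Dispatch to one of the tree builders by name ("upgma", "nj", "bionj")."""
    if method not in TREE_METHODS:
        raise ValueError(f"unknown tree method {method!r}; choose from {TREE_METHODS}")
    return {"upgma": upgma_tree, "nj": nj_tree, "bionj": bionj_tree}[method](matrix)


def leaf_labels(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def root_with_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root the tree on the branch leading to the named leaf.

    The outgroup becomes one child of the new root; ingroup splits are
    unchanged.
    """
    if outgroup_label not in leaf_labels(tree):
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    return tree.root_by_outgroup([outgroup_label])


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference count of nontrivial bipartitions (unrooted RF)."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ; symmetric difference {sorted(l1 ^ l2)}"
        )
    a, b = t1.copy(), t2.copy()
    a.unroot()
    b.unroot()
    return int(round(a.compare_rfd(b, rooted=False)))


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree file into a TreeNode."""
    tree = TreeNode.read(str(path), format="newick")
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate leaf labels in {path}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths; errors on duplicate leaves."""
    labels = [t.name for t in tree.tips()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels; refusing to write ambiguous Newick")
    tree.write(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
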