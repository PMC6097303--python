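"""Neighbor-joining trees of element copies and tree-imbalance metrics.

Copy phylogenies discriminate between two amplification modes: a
"master copy" mode, where one active element is serially replaced and
the copy tree is highly unbalanced (caterpillar-like), and a
"transposon" mode where all copies amplify at similar rates and the
tree is balanced. The normalized Colless index quantifies this on the
midpoint-rooted NJ tree of pairwise Kimura distances.
"""
from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .core import PolyteError


@dataclass
class PhyloResult:
    newick: str
    leaf_ids: tuple
    colless_normalized: float
    leaf_subgenomes: Optional[Dict[str, str]] = None


def nj_tree(ids: Sequence[str], distances: np.ndarray) -> TreeNode:
    """Midpoint-rooted neighbor-joining tree from a distance matrix.

    Leaf order is canonicalized (sorted ids) before joining so the result
    does not depend on input order.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise PolyteError("NJ requires at least 3 leaves")
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(distances, distances.T) or not np.allclose(np.diag(distances), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    order = np.argsort(ids)
    dm = DistanceMatrix(distances[np.ix_(order, order)], [ids[i] for i in order])
    tree = nj(dm)
    return tree.root_at_midpoint()


def _leaf_count(node: TreeNode, cache: dict) -> int:
    if node.is_tip():
        return 1
    if id(node) not in cache:
        cache[id(node)] = sum(_leaf_count(c, cache) for c in node.children)
    return cache[id(node)]


def colless_imbalance(tree: Union[TreeNode, str]) -> float:
    """Normalized Colless imbalance of a rooted binary tree, in [0, 1].

    Sum over internal nodes of |leaves(left) - leaves(right)|, divided by
    the caterpillar maximum (n-1)(n-2)/2.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(StringIO(tree))
    n = tree.count(tips=True)
    if n < 3:
        raise PolyteError("Colless index requires >= 3 leaves")
    cache: dict = {}
    total = 0
    for node in tree.non_tips(include_self=True):
        kids = node.children
        if len(kids) != 2:
            raise PolyteError(
                f"non-binary node with {len(kids)} children; Colless needs a binary tree"
            )
        total += abs(_leaf_count(kids[0], cache) - _leaf_count(kids[1], cache))
    return total / ((n - 1) * (n - 2) / 2)


def cluster_tree(
    ids: Sequence[str],
    distances: np.ndarray,
    subgenome_by_id: Optional[Mapping[str, str]] = None,
) -> PhyloResult:
    """NJ tree plus Colless imbalance for one cluster of elements."""
    tree = nj_tree(ids, distances)
    newick = str(tree).strip()
    leaf_ids = tuple(sorted(t.name for t in tree.tips()))
    colless = colless_imbalance(tree)
    leaf_sg = (
        {i: subgenome_by_id[i] for i in leaf_ids} if subgenome_by_id is not None else None
    )
    return PhyloResult(newick, leaf_ids, colless, leaf_sg)
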