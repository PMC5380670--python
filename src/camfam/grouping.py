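"""Distance-based grouping of the family: NJ tree over identity distances.

The distance between two proteins is 100 minus their shorter-sequence
percent identity, so identical proteins sit at distance 0 and unrelated
ones near 100. A neighbor-joining tree built on this matrix separates the
highly conserved CaMs from the divergent CMLs; cutting its longest
branches yields the family's group partition.

Cutting rule: branches (internal first by length) are removed in order of
decreasing length until the leaves fall into the requested number of
groups; alternatively all branches longer than a threshold are removed.
Ties in branch length break deterministically by the alphabetically first
leaf name below the branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .identity import AlignParams, percent_identity_pair
from .seqio import ProteinRecord

__all__ = ["DistanceTree", "identity_distance_matrix", "build_distance_tree", "cut_groups"]


@dataclass
class DistanceTree:
    """An NJ tree plus the distance matrix it was built from."""

    tree: TreeNode
    leaves: list[str]
    source_distances: DistanceMatrix

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def identity_distance_matrix(
    records: list[ProteinRecord], params: AlignParams = AlignParams()
) -> DistanceMatrix:
    """Symmetric matrix of (100 - percent identity) over all pairs."""
    ids = [r.id for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if records[i].seq == records[j].seq:
                d = 0.0
            else:
                d = 100.0 - percent_identity_pair(records[i], records[j], params)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def build_distance_tree(
    records: list[ProteinRecord], params: AlignParams = AlignParams()
) -> DistanceTree:
    """Neighbor-joining tree over pairwise identity distances.

    Deterministic given input order; negative NJ branch lengths are clamped
    to zero and all lengths rounded to 6 decimals for stable serialization.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to build a tree")
    dm = identity_distance_matrix(records, params)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(max(node.length, 0.0), 6)
    return DistanceTree(tree=tree, leaves=list(dm.ids), source_distances=dm)


def _tree_graph(tree: TreeNode) -> tuple[nx.Graph, list[tuple]]:
    """Undirected graph of the tree plus its branch list.

    Each branch is (length, tiebreak_name, parent_node, child_node) where
    tiebreak_name is the alphabetically first leaf below the child.
    """
    graph = nx.Graph()
    branches = []
    for node in tree.traverse(include_self=True):
        graph.add_node(id(node), is_leaf=node.is_tip(), name=node.name)
        if node.parent is not None:
            graph.add_edge(id(node.parent), id(node))
            below = sorted(t.name for t in ([node] if node.is_tip() else node.tips()))
            branches.append((float(node.length or 0.0), below[0], node))
    return graph, branches


def _leaf_partition(graph: nx.Graph) -> list[set[str]]:
    parts = []
    for comp in nx.connected_components(graph):
        leaves = {graph.nodes[n]["name"] for n in comp if graph.nodes[n]["is_leaf"]}
        if leaves:
            parts.append(leaves)
    return sorted(parts, key=lambda s: sorted(s)[0])


def cut_groups(
    dtree: DistanceTree,
    k: int | None = None,
    threshold: float | None = None,
) -> list[set[str]]:
    """Partition the leaves into groups by removing the longest branches.

    Exactly one of ``k`` (number of groups) or ``threshold`` (remove all
    branches longer than this) must be given. Internal branches are
    preferred over terminal ones at equal length.
    """
    if (k is None) == (threshold is None):
        raise ValueError("give exactly one of k or threshold")
    graph, branches = _tree_graph(dtree.tree)
    n_leaves = len(dtree.leaves)
    if k is not None:
        if not 1 <= k <= n_leaves:
            raise ValueError(f"k={k} outside [1, {n_leaves}]")
        # Internal branches first (longest to shortest), then terminal ones:
        # splitting between clades precedes splitting off single leaves.
        # Ties break by the alphabetically first leaf name below the branch.
        order = sorted(
            branches, key=lambda b: (b[2].is_tip(), -b[0], b[1])
        )
        for length, _name, node in order:
            if len(_leaf_partition(graph)) >= k:
                break
            graph.remove_edge(id(node.parent), id(node))
        return _leaf_partition(graph)
    for length, _name, node in branches:
        if length > threshold:
            graph.remove_edge(id(node.parent), id(node))
    return _leaf_partition(graph)
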