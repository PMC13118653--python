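"""Phylogeny handling: Newick I/O, pruning to an OTU table, patristic distances.

Trees are ``skbio.TreeNode`` objects throughout. Internal-node support
values are parsed (as node names) but play no role in any distance or
diversity computation.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import DistanceMatrix, TreeNode

from rivasm.tables import CommunityTable

__all__ = ["read_tree", "tree_from_newick", "prune_to_table", "patristic_matrix", "total_branch_length"]


def _validate(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    return tree


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Missing branch lengths default to 0; negative lengths are rejected
    (meaningless for phylogenetic diversity and patristic math).
    """
    tree = TreeNode.read(str(path), format="newick")
    return _validate(tree)


def tree_from_newick(newick: str) -> TreeNode:
    """Parse a Newick string (convenience for tests and simulators)."""
    return _validate(TreeNode.read(io.StringIO(newick), format="newick"))


def prune_to_table(tree: TreeNode, table) -> TreeNode:
    """Prune the tree so its leaf set equals the table's OTU registry.

    Degree-2 internal nodes left by pruning are collapsed with branch
    lengths summed, so patristic distances among retained leaves are
    conserved exactly.
    """
    if isinstance(table, CommunityTable):
        wanted = set(table.otu_ids)
    else:
        wanted = set(str(x) for x in table)
    have = {t.name for t in tree.tips()}
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    pruned = tree.shear(wanted)
    pruned.prune()
    return _validate(pruned)


def patristic_matrix(tree: TreeNode, otu_ids=None) -> DistanceMatrix:
    """All pairwise leaf-to-leaf path lengths.

    Returns a ``skbio.DistanceMatrix`` over the tree's leaves (reordered to
    ``otu_ids`` when given).
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("patristic matrix requires at least two leaves")
    dm = tree.tip_tip_distances()
    if otu_ids is not None:
        dm = dm.filter([str(o) for o in otu_ids])
    return dm


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))
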