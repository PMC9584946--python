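"""Rooted phylogenies over OTU identifiers (newick I/O, pruning).

Trees are held as :class:`skbio.TreeNode`. Pruning keeps an exact leaf set
and collapses the unary internal nodes this creates by summing their branch
lengths, so every kept leaf's root-to-leaf path length is unchanged — the
property that makes weighted UniFrac invariant to pruning of absent taxa.
"""

from __future__ import annotations

from skbio import TreeNode

__all__ = ["read_tree", "write_tree", "prune_tree", "leaf_names"]


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    names = leaf_names(tree)
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def leaf_names(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def prune_tree(tree: TreeNode, keep_ids) -> TreeNode:
    """Return a copy of ``tree`` restricted to the leaves in ``keep_ids``.

    Unary internal nodes produced by the restriction are collapsed with their
    branch lengths summed. Raises ``KeyError`` if any requested leaf is
    absent.
    """
    keep = list(dict.fromkeys(keep_ids))
    present = set(leaf_names(tree))
    missing = [k for k in keep if k not in present]
    if missing:
        raise KeyError(f"leaves not in tree: {missing}")
    pruned = tree.shear(keep)
    # shear merges unary chains edge-to-edge (safe: both edges subtend the
    # same leaf set) but can leave the collapsed stem above the kept taxa's
    # ancestor as a dangling root length, which no root-to-leaf path would
    # count; keep that stem as an explicit unary root edge instead so both
    # path lengths and every branch's subtended leaf set are preserved
    if pruned.length:
        new_root = TreeNode()
        new_root.append(pruned)
        return new_root
    return pruned
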