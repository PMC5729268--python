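"""Species-tree helpers shared by the simulator and the marker mapper.

Trees are plain :class:`dendropy.Tree` objects (rooted, leaf labels unique).
A *branch* is the edge above a node and is identified by the set of leaf
labels it subtends, serialised as the comma-joined sorted label list, e.g.
``"Menura,Taeniopygia"``.  This makes branch identifiers stable across
newick round trips and independent of internal node labels.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = [
    "load_tree",
    "tree_from_newick",
    "leaf_labels",
    "branch_id",
    "clade_of",
    "iter_branches",
    "resolve_branch",
    "validate_species_tree",
]


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a rooted newick string into a dendropy tree."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    validate_species_tree(tree)
    return tree


def load_tree(path: str) -> dendropy.Tree:
    """Read a rooted newick tree from *path*."""
    with open(path) as fh:
        return tree_from_newick(fh.read())


def validate_species_tree(tree: dendropy.Tree) -> None:
    """Check rootedness, unique leaf labels and non-negative branch lengths."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) == 0:
        raise ValueError("tree has no leaves")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clade_of(node: dendropy.Node) -> frozenset[str]:
    """Leaf-label set subtended by *node*."""
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def branch_id(node: dendropy.Node) -> str:
    """Stable identifier of the branch above *node*."""
    return ",".join(sorted(clade_of(node)))


def iter_branches(tree: dendropy.Tree) -> Iterator[dendropy.Node]:
    """Every non-root node, i.e. every branch of the rooted tree."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            yield node


def resolve_branch(tree: dendropy.Tree, branch_spec: str) -> dendropy.Node:
    """Find the branch named by *branch_spec*.

    *branch_spec* is either a single leaf label or a comma-separated set of leaf
    labels; the branch returned is the one whose subtended clade equals that
    set exactly.
    """
    want = frozenset(s.strip() for s in branch_spec.split(",") if s.strip())
    if not want:
        raise ValueError("empty branch specification")
    for node in iter_branches(tree):
        if clade_of(node) == want:
            return node
    raise KeyError(f"no branch subtends exactly {sorted(want)}")
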