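"""Gall removal.

Removing a gall while keeping the leaf set: delete the hybrid node and one
hybridizing side node, then join (i) the surviving hybridizing node to the
hybrid's child and (ii) the deleted node's parent to its remaining child.
Every labeled history of the original tree maps to one of the result — the
hybridization set is replaced by the surviving hybridizing node — so the
transform never decreases the number of labeled histories.
"""

from __future__ import annotations

from .errors import GallhistError
from .model import Gall, GalledTree, off_cycle_child


def remove_gall(tree: GalledTree, gall: Gall, side: str = "right") -> GalledTree:
    """Remove one gall, preserving leaves and dropping the gall count by one.

    ``side`` names the hybridizing side node to delete ("right" by
    default; the choice is arbitrary and both give isomorphic results for
    reflected galls, though not in general).
    """
    if side not in ("left", "right"):
        raise GallhistError("side must be 'left' or 'right'")
    if side == "right":
        removed, kept = gall.right_hybridizing, gall.left_hybridizing
    else:
        removed, kept = gall.left_hybridizing, gall.right_hybridizing

    hybrid_child = off_cycle_child(tree, gall, gall.hybrid)
    removed_child = off_cycle_child(tree, gall, removed)
    (removed_parent,) = tree.parents[removed]

    children = {u: list(cs) for u, cs in tree.children.items()}
    children[kept] = [
        hybrid_child if c == gall.hybrid else c for c in children[kept]
    ]
    children[removed_parent] = [
        removed_child if c == removed else c for c in children[removed_parent]
    ]
    del children[gall.hybrid]
    del children[removed]
    return GalledTree(children, tree.root, tree.leaf_labels)
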