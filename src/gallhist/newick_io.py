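"""Extended-Newick (eNewick) reading and writing for galled trees.

The dialect is the widely used one for phylogenetic networks: each hybrid
node carries a reticulation tag ``#H<k>`` and appears exactly twice — once
with its subtree (under either parent), once as a bare reference — e.g.::

    ((d,(e)#H2),(#H2,f));

is the three-leaf tree whose single gall has hybridizing nodes bearing
leaves ``d`` and ``f`` and a hybrid node bearing leaf ``e``.  General
phylogenetics libraries do not represent reticulations, so the parser and
writer are implemented here.  Branch lengths, if present, are parsed and
discarded with a warning; the model is topology-only.  Leaf labels must be
unique.

The writer emits a canonical form: children ordered by canonical shape
(ties broken by leaf labels), each gall oriented by its canonical
reflection, and each hybrid subtree attached at its first-written parent.
``parse_enewick(write_enewick(t))`` is always isomorphic to ``t``, and
``write_enewick`` is the identity on its own output.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .enumeration import canonical_shape
from .errors import NotAGalledTreeError, ParseError, UnmatchedHybridTagError
from .model import (
    GalledTree,
    find_galls,
    off_cycle_child,
    subtree_nodes,
    tree_to_shape,
    validate,
)

__all__ = ["parse_enewick", "write_enewick", "read_enewick_file", "write_enewick_file"]


@dataclass
class _RawNode:
    children: List["_RawNode"] = field(default_factory=list)
    name: str = ""
    tag: Optional[str] = None


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> ParseError:
        return ParseError(f"{message} (at position {self.pos})")

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> _RawNode:
        node = self.parse_node()
        if self.peek() != ";":
            raise self.error("expected ';' at end of tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing text after ';'")
        return node

    def parse_node(self) -> _RawNode:
        node = _RawNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.parse_node())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.parse_node())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
        label = self.parse_label()
        if "#" in label:
            name, _, tag = label.partition("#")
            if not tag:
                raise self.error("empty reticulation tag")
            node.name, node.tag = name, tag
        else:
            node.name = label
        if self.peek() == ":":  # branch length: parsed, ignored
            self.pos += 1
            start = self.pos
            while self.peek() not in (",", ")", ";", ""):
                self.pos += 1
            try:
                float(self.text[start : self.pos])
            except ValueError:
                raise self.error("malformed branch length")
            warnings.warn(
                "branch lengths are not part of the model and were discarded",
                stacklevel=4,
            )
        return node

    def parse_label(self) -> str:
        self.skip_ws()
        start = self.pos
        while (
            self.pos < len(self.text)
            and self.text[self.pos] not in "(),;:"
            and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        return self.text[start : self.pos]


def parse_enewick(text: str) -> GalledTree:
    """Parse one eNewick string into a validated :class:`GalledTree`.

    Raises :class:`ParseError` on syntax errors,
    :class:`UnmatchedHybridTagError` if a reticulation tag does not appear
    exactly twice (once with a subtree, once bare), and
    :class:`NotAGalledTreeError` (with the validation report attached) if
    the network parsed is not a galled tree.
    """
    raw_root = _Parser(text.strip()).parse()

    counter = itertools.count(1)
    children: Dict[int, List[int]] = {}
    leaf_labels: Dict[int, str] = {}
    hybrid_ids: Dict[str, int] = {}
    tag_defs: Dict[str, int] = {}
    tag_refs: Dict[str, int] = {}

    def build(raw: _RawNode) -> int:
        if raw.tag is not None:
            nid = hybrid_ids.setdefault(raw.tag, next(counter))
            children.setdefault(nid, [])
            if raw.children:
                tag_defs[raw.tag] = tag_defs.get(raw.tag, 0) + 1
                if len(raw.children) != 1:
                    raise ParseError(
                        f"hybrid #{raw.tag} must carry exactly one subtree"
                    )
                children[nid] = [build(raw.children[0])]
            else:
                tag_refs[raw.tag] = tag_refs.get(raw.tag, 0) + 1
            return nid
        nid = next(counter)
        if raw.children:
            children[nid] = [build(c) for c in raw.children]
        else:
            if not raw.name:
                raise ParseError("leaf with empty label")
            children[nid] = []
            leaf_labels[nid] = raw.name
        return nid

    root = build(raw_root)
    for tag in set(tag_defs) | set(tag_refs):
        d, r = tag_defs.get(tag, 0), tag_refs.get(tag, 0)
        if (d, r) != (1, 1):
            raise UnmatchedHybridTagError(
                f"reticulation tag #{tag} must appear exactly twice (one "
                f"subtree-bearing, one bare reference); found {d} definition(s) "
                f"and {r} reference(s)"
            )
    labels = list(leaf_labels.values())
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ParseError(f"duplicate leaf labels: {dupes}")

    tree = GalledTree(children, root, leaf_labels)
    report = validate(tree)
    if not report:
        raise NotAGalledTreeError(
            f"parsed network is not a galled tree: [{report.code}] {report.message}",
            report=report,
        )
    return tree


def write_enewick(tree: GalledTree) -> str:
    """Serialize to canonical eNewick (deterministic; ends with ';')."""
    galls_by_top = {g.top: g for g in find_galls(tree)}
    tag_counter = itertools.count(1)

    def sort_key(node):
        shape = canonical_shape(tree_to_shape(tree, node))
        labels = sorted(
            tree.leaf_labels[u] for u in subtree_nodes(tree, node) if tree.is_leaf(u)
        )
        return (shape, labels)

    def render(node) -> str:
        if tree.is_leaf(node):
            return tree.leaf_labels[node]
        gall = galls_by_top.get(node)
        if gall is not None:
            shape = tree_to_shape(tree, node)
            # orient by canonical reflection
            parts = tuple(canonical_shape(p) for p in shape[2])
            m_right = len(parts) - 3 - shape[1]
            if ("G", m_right, tuple(reversed(parts))) < ("G", shape[1], parts):
                gall = gall.reflected()
            tag = f"H{next(tag_counter)}"
            hybrid_sub = render(off_cycle_child(tree, gall, gall.hybrid))
            left_expr = f"({render(off_cycle_child(tree, gall, gall.left_hybridizing))},({hybrid_sub})#{tag})"
            for s in reversed(gall.left_side):
                left_expr = f"({render(off_cycle_child(tree, gall, s))},{left_expr})"
            right_expr = (
                f"(#{tag},{render(off_cycle_child(tree, gall, gall.right_hybridizing))})"
            )
            for s in reversed(gall.right_side):
                right_expr = f"({right_expr},{render(off_cycle_child(tree, gall, s))})"
            return f"({left_expr},{right_expr})"
        c1, c2 = sorted(tree.children[node], key=sort_key)
        return f"({render(c1)},{render(c2)})"

    return render(tree.root) + ";"


def read_enewick_file(path) -> List[GalledTree]:
    """Read trees from a UTF-8 text file, one eNewick per line."""
    trees = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_enewick(line))
    return trees


def write_enewick_file(trees, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(write_enewick(t) + "\n")
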