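"""Rooted binary galled trees.

A *galled tree* is a rooted binary phylogenetic network (a directed acyclic
graph with one in-degree-0/out-degree-2 root, in-degree-1/out-degree-0
leaves, and internal nodes of degree (1,2) or (2,1)) in which every
reticulation node lies on exactly one undirected cycle — a *gall* — and the
galls are pairwise vertex-disjoint and not nested.  Reticulation nodes are
called *hybrid* nodes; each gall consists of a *top* node, a hybrid node,
the two parents of the hybrid (*hybridizing side nodes*), and any number of
*non-hybridizing side nodes* along the two top-to-hybrid paths.

Time runs from the root to the leaves.  A hybrid node is simultaneous with
its two parents, so a hybridization contributes a single *event*; every
other internal tree node is a coalescence event.  A galled tree with ``n``
leaves therefore has exactly ``n - 1`` events regardless of its gall count.

This module provides the :class:`GalledTree` container, gall detection,
structural validation, subtree extraction around a gall, and the
shape-tuple encoding used by the enumeration machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .errors import (
    DegreeViolationError,
    GallhistError,
    InfeasibleError,
    NestedCyclesError,
    NotRootedDAGError,
    SharedCycleVerticesError,
    TemporallyInconsistentError,
)

Node = int
#: Shape-tuple encoding of an unlabeled galled tree:
#:   ``("L",)``                      a leaf;
#:   ``("T", a, b)``                 a tree node with child shapes a, b;
#:   ``("G", n_left, parts)``        a gall, where ``parts`` lists the shapes
#:                                   of the gall's subtrees in composition
#:                                   order (most ancestral left side node,
#:                                   ..., left hybridizing node, hybrid node,
#:                                   right hybridizing node, ..., most
#:                                   ancestral right side node) and
#:                                   ``n_left`` is the number of
#:                                   non-hybridizing side nodes on the left.
Shape = tuple
LEAF: Shape = ("L",)


class GalledTree:
    """A rooted binary galled tree (topology only, no branch lengths).

    Parameters
    ----------
    children:
        Mapping from node to an ordered tuple of its children.  Leaves may
        be omitted or mapped to an empty tuple.  Child order is stored but
        carries no meaning for counting: all computations are invariant
        under swapping the children of any node.
    root:
        The root node.
    leaf_labels:
        Mapping from leaf node to its label string.
    """

    __slots__ = ("children", "parents", "root", "leaf_labels")

    def __init__(
        self,
        children: Dict[Node, Sequence[Node]],
        root: Node,
        leaf_labels: Dict[Node, str],
    ):
        self.children: Dict[Node, Tuple[Node, ...]] = {
            u: tuple(cs) for u, cs in children.items()
        }
        for u, cs in list(self.children.items()):
            for c in cs:
                if c not in self.children:
                    self.children[c] = ()
        if root not in self.children:
            self.children[root] = ()
        self.root = root
        self.leaf_labels = dict(leaf_labels)
        parents: Dict[Node, List[Node]] = {u: [] for u in self.children}
        for u, cs in self.children.items():
            for c in cs:
                parents[c].append(u)
        self.parents: Dict[Node, Tuple[Node, ...]] = {
            u: tuple(ps) for u, ps in parents.items()
        }

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> List[Node]:
        return list(self.children)

    @property
    def edges(self) -> List[Tuple[Node, Node]]:
        return [(u, c) for u, cs in self.children.items() for c in cs]

    def is_leaf(self, u: Node) -> bool:
        return not self.children[u]

    @property
    def leaves(self) -> List[Node]:
        return [u for u in self.children if not self.children[u]]

    @property
    def internal_nodes(self) -> List[Node]:
        return [u for u in self.children if self.children[u]]

    @property
    def hybrid_nodes(self) -> List[Node]:
        return [u for u in self.children if len(self.parents[u]) == 2]

    @property
    def n(self) -> int:
        """Number of leaves."""
        return len(self.leaves)

    @property
    def g(self) -> int:
        """Number of galls (equivalently, hybrid nodes)."""
        return len(self.hybrid_nodes)

    def in_degree(self, u: Node) -> int:
        return len(self.parents[u])

    def out_degree(self, u: Node) -> int:
        return len(self.children[u])

    def to_networkx(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.children)
        dg.add_edges_from(self.edges)
        return dg

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GalledTree(n={self.n}, g={self.g}, root={self.root!r})"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_shape(
        cls, shape: Shape, labels: Optional[Iterable[str]] = None
    ) -> "GalledTree":
        """Materialize a shape tuple into a concrete tree.

        Leaves are labeled from ``labels`` in left-to-right order, or
        ``L1..Ln`` by default.
        """
        counter = itertools.count(1)
        children: Dict[Node, List[Node]] = {}
        leaves: List[Node] = []

        def build(s: Shape) -> Node:
            nid = next(counter)
            if s[0] == "L":
                children[nid] = []
                leaves.append(nid)
            elif s[0] == "T":
                children[nid] = [build(s[1]), build(s[2])]
            elif s[0] == "G":
                n_left = s[1]
                parts = s[2]
                if len(parts) < 3:
                    raise GallhistError("a gall needs at least three subtrees")
                # parts: [left sides ancestral-first] + [T_L, T_C, T_R]
                #        + [right sides descendant-first]
                hybrid = None

                def chain(part_shapes: Sequence[Shape], bottom: Node) -> Node:
                    # Build side-node chain from the most descendant upward.
                    below = bottom
                    for ps in reversed(part_shapes):
                        side = next(counter)
                        children[side] = [build(ps), below]
                        below = side
                    return below

                hybrid = next(counter)
                children[hybrid] = [build(parts[n_left + 1])]
                left_hyb = next(counter)
                children[left_hyb] = [build(parts[n_left]), hybrid]
                right_hyb = next(counter)
                children[right_hyb] = [hybrid, build(parts[n_left + 2])]
                left_top = chain(parts[:n_left], left_hyb)
                right_top = chain(list(reversed(parts[n_left + 3 :])), right_hyb)
                children[nid] = [left_top, right_top]
            else:  # pragma: no cover
                raise GallhistError(f"unknown shape tag {s[0]!r}")
            return nid

        root = build(shape)
        if labels is None:
            labels = [f"L{i}" for i in range(1, len(leaves) + 1)]
        label_list = list(labels)
        if len(label_list) != len(leaves):
            raise GallhistError("label count does not match leaf count")
        return cls(children, root, dict(zip(leaves, label_list)))


@dataclass(frozen=True)
class Gall:
    """Anatomy of one gall.

    ``left_side`` / ``right_side`` list the non-hybridizing side nodes of
    each path in ancestral-first order.  The left/right assignment follows
    the stored child order of the top node; it is display orientation only
    and never affects counts.
    """

    top: Node
    hybrid: Node
    left_hybridizing: Node
    right_hybridizing: Node
    left_side: Tuple[Node, ...]
    right_side: Tuple[Node, ...]

    @property
    def N(self) -> int:
        return len(self.left_side)

    @property
    def M(self) -> int:
        return len(self.right_side)

    @property
    def cycle_nodes(self) -> frozenset:
        return frozenset(
            (self.top, self.hybrid, self.left_hybridizing, self.right_hybridizing)
            + self.left_side
            + self.right_side
        )

    def reflected(self) -> "Gall":
        """Swap the two sides (an isomorphism of the gall)."""
        return Gall(
            self.top,
            self.hybrid,
            self.right_hybridizing,
            self.left_hybridizing,
            self.right_side,
            self.left_side,
        )


@dataclass
class GallSubtrees:
    """The subtrees hanging off one gall.

    ``left_subtrees``/``right_subtrees`` follow the ancestral-first order of
    the gall's side nodes; ``L``, ``C``, ``R`` are the subtrees of the left
    hybridizing node, the hybrid node, and the right hybridizing node.
    """

    left_subtrees: List[GalledTree]
    L: GalledTree
    C: GalledTree
    R: GalledTree
    right_subtrees: List[GalledTree]

    def row_order(self) -> List[GalledTree]:
        """Fixed subtree order used for assignment-matrix rows."""
        return [*self.left_subtrees, *self.right_subtrees, self.L, self.R, self.C]

    def composition_order(self) -> List[GalledTree]:
        """Subtrees in composition order (around the gall, left to right)."""
        return [
            *self.left_subtrees,
            self.L,
            self.C,
            self.R,
            *reversed(self.right_subtrees),
        ]

    @property
    def leaf_total(self) -> int:
        return sum(t.n for t in self.row_order())


@dataclass
class LabeledHistory:
    """A temporal ranking of a galled tree's nodes.

    ``ranking`` is the sequence of simultaneity sets ``W_1 .. W_n``: the
    root first, then one set per event (a singleton coalescence or a
    hybridization triple {hybrid, both parents}), and finally the leaf set.
    """

    ranking: List[frozenset]

    def check(self, tree: GalledTree) -> None:
        """Raise if this ranking is not a valid labeled history of *tree*."""
        n = tree.n
        if len(self.ranking) != n:
            raise GallhistError(f"ranking has {len(self.ranking)} sets, expected {n}")
        if self.ranking[0] != frozenset({tree.root}):
            raise GallhistError("W_1 must contain exactly the root")
        if self.ranking[-1] != frozenset(tree.leaves):
            raise GallhistError("W_n must contain exactly the leaves")
        seen = set()
        position = {}
        for i, w in enumerate(self.ranking):
            if seen & w:
                raise GallhistError("node appears in two sets")
            seen |= w
            for v in w:
                position[v] = i
        if seen != set(tree.nodes):
            raise GallhistError("ranking does not cover all nodes")
        for w in self.ranking[:-1]:
            if len(w) == 1:
                (v,) = w
                if tree.in_degree(v) == 2:
                    raise GallhistError("hybrid node ranked without its parents")
            elif len(w) == 3:
                hybrids = [v for v in w if tree.in_degree(v) == 2]
                if len(hybrids) != 1 or set(tree.parents[hybrids[0]]) != w - {hybrids[0]}:
                    raise GallhistError("triple is not a hybridization")
            else:
                raise GallhistError("sets must be singletons or hybrid triples")
        for u, v in tree.edges:
            if position[u] > position[v]:
                raise GallhistError("ranking violates ancestry")


# -- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    ok: bool
    code: Optional[str] = None
    message: str = ""

    def __bool__(self) -> bool:
        return self.ok


_ERROR_CLASSES = {
    "NOT_ROOTED_DAG": NotRootedDAGError,
    "DEGREE_VIOLATION": DegreeViolationError,
    "NESTED_CYCLES": NestedCyclesError,
    "SHARED_CYCLE_VERTICES": SharedCycleVerticesError,
    "TEMPORALLY_INCONSISTENT": TemporallyInconsistentError,
}


def _chain_up(tree: GalledTree, node: Node) -> List[Node]:
    """Walk up unique parents from *node*; stop at the root or a hybrid."""
    out = [node]
    cur = node
    while tree.in_degree(cur) == 1:
        cur = tree.parents[cur][0]
        out.append(cur)
        if len(out) > len(tree.children):  # cycle guard for invalid input
            break
    return out


def _find_gall_for_hybrid(tree: GalledTree, hybrid: Node) -> Gall:
    p1, p2 = tree.parents[hybrid]
    chain1 = _chain_up(tree, p1)
    chain2 = _chain_up(tree, p2)
    in2 = set(chain2)
    top = next((u for u in chain1 if u in in2), None)
    if top is None:
        raise NestedCyclesError(
            f"no clean cycle for hybrid {hybrid}: a top-to-hybrid path passes "
            "through another reticulation"
        )
    if top in (p1, p2):
        raise DegreeViolationError(
            f"gall top {top} is itself a parent of hybrid {hybrid}; every "
            "hybridizing side node must carry an off-cycle subtree"
        )
    i1 = chain1.index(top)
    i2 = chain2.index(top)
    path1 = chain1[:i1]  # p1 .. node just below top
    path2 = chain2[:i2]
    # Orient by the stored child order of the top node.
    first_child = tree.children[top][0]
    if path1[-1] == first_child:
        left_path, right_path = path1, path2
        left_hyb, right_hyb = p1, p2
    else:
        left_path, right_path = path2, path1
        left_hyb, right_hyb = p2, p1
    left_side = tuple(reversed(left_path[1:]))  # ancestral-first, no hybridizing
    right_side = tuple(reversed(right_path[1:]))
    return Gall(top, hybrid, left_hyb, right_hyb, left_side, right_side)


def find_galls(tree: GalledTree) -> List[Gall]:
    """One :class:`Gall` per hybrid node, in node-insertion order."""
    return [_find_gall_for_hybrid(tree, h) for h in tree.hybrid_nodes]


def event_graph(tree: GalledTree):
    """Directed graph on events (hybridization triples contracted).

    Returns ``(graph, event_of)`` where ``event_of`` maps each internal
    node to its event key: ``("coal", node)`` for an ordinary coalescence
    or ``("hyb", hybrid)`` for any member of a hybridization triple.
    """
    event_of = {}
    for u in tree.internal_nodes:
        if tree.in_degree(u) == 2:
            event_of[u] = ("hyb", u)
            for p in tree.parents[u]:
                event_of[p] = ("hyb", u)
    for u in tree.internal_nodes:
        event_of.setdefault(u, ("coal", u))
    dg = nx.DiGraph()
    dg.add_nodes_from(set(event_of.values()))
    for u, v in tree.edges:
        if tree.is_leaf(v):
            continue
        eu, ev = event_of[u], event_of[v]
        if eu != ev:
            dg.add_edge(eu, ev)
    return dg, event_of


def validate(tree: GalledTree, raise_on_error: bool = False) -> ValidationReport:
    """Check all galled-tree conditions; report the first violation.

    Conditions, in the order tested: rooted DAG reachable from the root;
    binary degree constraints; each hybrid node has a clean gall (two
    node-disjoint top-to-hybrid paths, no nesting); galls pairwise
    vertex-disjoint; the contracted event order admits a time function
    (no temporal impossibility among hybridizations).
    """

    def fail(code: str, message: str) -> ValidationReport:
        if raise_on_error:
            raise _ERROR_CLASSES[code](message)
        return ValidationReport(False, code, message)

    dg = tree.to_networkx()
    if tree.root not in tree.children or tree.in_degree(tree.root) != 0:
        return fail("NOT_ROOTED_DAG", "root must exist with in-degree 0")
    if not nx.is_directed_acyclic_graph(dg):
        return fail("NOT_ROOTED_DAG", "graph has a directed cycle")
    reachable = {tree.root} | nx.descendants(dg, tree.root)
    if reachable != set(tree.children):
        stray = sorted(set(tree.children) - reachable)
        return fail("NOT_ROOTED_DAG", f"nodes not reachable from root: {stray}")

    if tree.n == 1:
        if len(tree.children) != 1:
            return fail("DEGREE_VIOLATION", "single-leaf tree must be one node")
        return ValidationReport(True)
    for u in tree.children:
        ind, outd = tree.in_degree(u), tree.out_degree(u)
        if u == tree.root:
            ok = (ind, outd) == (0, 2)
        elif tree.is_leaf(u):
            ok = (ind, outd) == (1, 0)
        else:
            ok = (ind, outd) in ((1, 2), (2, 1))
        if not ok:
            return fail(
                "DEGREE_VIOLATION", f"node {u} has degrees (in={ind}, out={outd})"
            )

    galls = []
    for h in tree.hybrid_nodes:
        try:
            galls.append(_find_gall_for_hybrid(tree, h))
        except (NestedCyclesError, DegreeViolationError) as exc:
            return fail(exc.code, str(exc))
    for g1, g2 in itertools.combinations(galls, 2):
        shared = g1.cycle_nodes & g2.cycle_nodes
        if shared:
            return fail(
                "SHARED_CYCLE_VERTICES",
                f"galls of hybrids {g1.hybrid} and {g2.hybrid} share nodes "
                f"{sorted(shared)}",
            )

    eg, _ = event_graph(tree)
    if not nx.is_directed_acyclic_graph(eg):
        return fail(
            "TEMPORALLY_INCONSISTENT",
            "contracting hybridization triples creates a cycle among events; "
            "no time function exists",
        )
    return ValidationReport(True)


# -- structural accounting -------------------------------------------------


def event_count(tree: GalledTree) -> int:
    """Number of events: internal nodes minus twice the hybrid nodes.

    Each hybridization is three simultaneous internal nodes but one event,
    so the result equals ``n - 1`` for a valid galled tree.
    """
    return len(tree.internal_nodes) - 2 * len(tree.hybrid_nodes)


def subtree_nodes(tree: GalledTree, node: Node) -> set:
    out = set()
    stack = [node]
    while stack:
        u = stack.pop()
        if u in out:
            continue
        out.add(u)
        stack.extend(tree.children[u])
    return out


def extract_subtree(tree: GalledTree, node: Node) -> GalledTree:
    """Materialize the subtree rooted at *node* as its own GalledTree."""
    keep = subtree_nodes(tree, node)
    children = {u: tree.children[u] for u in keep}
    labels = {u: lab for u, lab in tree.leaf_labels.items() if u in keep}
    return GalledTree(children, node, labels)


def off_cycle_child(tree: GalledTree, gall: Gall, node: Node) -> Node:
    """The unique child of a gall node that is not on the gall's cycle."""
    if node == gall.hybrid:
        (c,) = tree.children[node]
        return c
    cycle = gall.cycle_nodes
    others = [c for c in tree.children[node] if c not in cycle]
    if len(others) != 1:
        raise GallhistError(f"node {node} does not have a unique off-cycle child")
    return others[0]


def gall_subtrees(tree: GalledTree, gall: Gall) -> GallSubtrees:
    """Extract the N + M + 3 subtrees hanging off *gall*."""
    return GallSubtrees(
        left_subtrees=[
            extract_subtree(tree, off_cycle_child(tree, gall, s))
            for s in gall.left_side
        ],
        L=extract_subtree(tree, off_cycle_child(tree, gall, gall.left_hybridizing)),
        C=extract_subtree(tree, off_cycle_child(tree, gall, gall.hybrid)),
        R=extract_subtree(tree, off_cycle_child(tree, gall, gall.right_hybridizing)),
        right_subtrees=[
            extract_subtree(tree, off_cycle_child(tree, gall, s))
            for s in gall.right_side
        ],
    )


def max_galls(n: int) -> int:
    """Largest feasible gall count for ``n`` leaves: floor((n-1)/2)."""
    if n < 1:
        raise InfeasibleError("need at least one leaf")
    return (n - 1) // 2


# -- shape encoding --------------------------------------------------------


def tree_to_shape(tree: GalledTree, node: Optional[Node] = None) -> Shape:
    """Encode (the subtree at) *node* as a shape tuple (labels dropped)."""
    galls_by_top = {g.top: g for g in find_galls(tree)}
    if node is None:
        node = tree.root

    def go(u: Node) -> Shape:
        if tree.is_leaf(u):
            return LEAF
        gall = galls_by_top.get(u)
        if gall is not None:
            parts = (
                [go(off_cycle_child(tree, gall, s)) for s in gall.left_side]
                + [
                    go(off_cycle_child(tree, gall, gall.left_hybridizing)),
                    go(off_cycle_child(tree, gall, gall.hybrid)),
                    go(off_cycle_child(tree, gall, gall.right_hybridizing)),
                ]
                + [
                    go(off_cycle_child(tree, gall, s))
                    for s in reversed(gall.right_side)
                ]
            )
            return ("G", gall.N, tuple(parts))
        c1, c2 = tree.children[u]
        return ("T", go(c1), go(c2))

    return go(node)


def shape_leaf_count(shape: Shape) -> int:
    if shape[0] == "L":
        return 1
    if shape[0] == "T":
        return shape_leaf_count(shape[1]) + shape_leaf_count(shape[2])
    return sum(shape_leaf_count(p) for p in shape[2])


def shape_gall_count(shape: Shape) -> int:
    if shape[0] == "L":
        return 0
    if shape[0] == "T":
        return shape_gall_count(shape[1]) + shape_gall_count(shape[2])
    return 1 + sum(shape_gall_count(p) for p in shape[2])


# -- display numbering -----------------------------------------------------


def postorder_numbering(tree: GalledTree) -> Dict[Node, int]:
    """Display numbering of internal nodes, child before parent.

    Within a gall the hybrid node's subtree is numbered first, the hybrid
    node before the hybridizing side nodes, left side nodes bottom-up
    before the right side, and the top node last.  This is a drawing
    convention only; node identity never depends on it.
    """
    galls_by_top = {g.top: g for g in find_galls(tree)}
    numbers: Dict[Node, int] = {}
    counter = itertools.count(1)

    def assign(u: Node) -> None:
        numbers[u] = next(counter)

    def visit(u: Node) -> None:
        if tree.is_leaf(u):
            return
        gall = galls_by_top.get(u)
        if gall is not None:
            for s in gall.left_side:
                visit(off_cycle_child(tree, gall, s))
            visit(off_cycle_child(tree, gall, gall.hybrid))
            visit(off_cycle_child(tree, gall, gall.left_hybridizing))
            visit(off_cycle_child(tree, gall, gall.right_hybridizing))
            assign(gall.hybrid)
            assign(gall.left_hybridizing)
            assign(gall.right_hybridizing)
            for s in reversed(gall.left_side):
                assign(s)
            for s in reversed(gall.right_side):
                visit(off_cycle_child(tree, gall, s))
                assign(s)
            assign(u)
        else:
            for c in tree.children[u]:
                visit(c)
            assign(u)

    visit(tree.root)
    return numbers
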