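"""Exact counting of labeled histories for galled trees.

For a gall-free tree the count is classical.  Recursively, a tree whose
root joins subtrees with v_l and v_r events has

    L_H(T) = L_H(T_l) * L_H(T_r) * C(v_l + v_r, v_r),

with L_H = 1 for a single leaf or a cherry; in closed form,

    L_H(T) = (n-1)! / prod_{i internal} v(T_i).

For a gall whose top node is the subtree root the count decomposes over
the gall's N + M + 3 subtrees (N left and M right non-hybridizing side
nodes, the two hybridizing nodes, the hybrid node):

1. interleave the left and right side nodes — C(N+M, N) arrangements,
   each creating N + M + 1 time periods (between consecutive ranked side
   nodes, then between the last side node and the hybridization, then
   after the hybridization);
2. for each arrangement, assign each subtree's events to the periods at
   or below its side node (stars and bars: C(v + p - 1, v) weak
   compositions per subtree, where p is the number of available periods;
   the three bottom subtrees have p = 1);
3. weight each assignment by the product over periods of the multinomial
   coefficient of that period's column of the assignment matrix;
4. multiply the summed weights by the product of the subtree history
   counts.

All arithmetic is exact arbitrary-precision integer; counts grow
super-exponentially and reach 10^7 already at 17 leaves.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .errors import HasGallsError
from .model import (
    Gall,
    GalledTree,
    GallSubtrees,
    Node,
    Shape,
    event_count,
    find_galls,
    gall_subtrees,
    off_cycle_child,
    validate,
)

__all__ = [
    "count_labeled_histories",
    "count_tree_closed",
    "count_tree_recursive",
    "count_gall",
    "gall_breakdown",
    "side_arrangements",
    "enumerate_assignments",
    "assignment_weight",
    "clear_cache",
]

AssignmentMatrix = Tuple[Tuple[int, ...], ...]

#: shared cache: canonical shape -> number of labeled histories
_SHAPE_CACHE: Dict[Shape, int] = {}


def clear_cache() -> None:
    _SHAPE_CACHE.clear()


# -- small combinatorial helpers ------------------------------------------


def multinomial(counts: Sequence[int]) -> int:
    """Multinomial coefficient (sum counts)! / prod counts!."""
    total = sum(counts)
    out = 1
    rem = total
    for c in counts:
        out *= math.comb(rem, c)
        rem -= c
    return out


def weak_compositions(total: int, parts: int) -> Iterator[Tuple[int, ...]]:
    """All ways to write ``total`` as an ordered sum of ``parts`` >= 0."""
    if parts == 0:
        if total == 0:
            yield ()
        return
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in weak_compositions(total - first, parts - 1):
            yield (first,) + rest


def _interleavings(left: Sequence, right: Sequence) -> Iterator[tuple]:
    """All merges of two sequences preserving within-sequence order."""
    n, m = len(left), len(right)
    for positions in itertools.combinations(range(n + m), n):
        posset = set(positions)
        li = iter(left)
        ri = iter(right)
        yield tuple(next(li) if i in posset else next(ri) for i in range(n + m))


# -- classical tree formulas ----------------------------------------------


def count_tree_closed(tree: GalledTree) -> int:
    """Closed form for a gall-free tree: (n-1)! / prod v(T_i)."""
    if tree.g > 0:
        raise HasGallsError(
            "closed form applies to gall-free trees only; use "
            "count_labeled_histories"
        )
    leaf_counts: Dict[Node, int] = {}

    def fill(u: Node) -> int:
        if tree.is_leaf(u):
            leaf_counts[u] = 1
        else:
            leaf_counts[u] = sum(fill(c) for c in tree.children[u])
        return leaf_counts[u]

    fill(tree.root)
    num = math.factorial(tree.n - 1)
    denom = 1
    for u in tree.internal_nodes:
        denom *= leaf_counts[u] - 1  # v(T_i) for a gall-free subtree
    q, r = divmod(num, denom)
    assert r == 0, "closed-form division must be exact"
    return q


def count_tree_recursive(left: GalledTree, right: GalledTree) -> int:
    """Combine two root subtrees: L_H(l) L_H(r) C(v_l + v_r, v_r)."""
    vl, vr = event_count(left), event_count(right)
    return (
        count_labeled_histories(left)
        * count_labeled_histories(right)
        * math.comb(vl + vr, vr)
    )


# -- gall machinery --------------------------------------------------------


def side_arrangements(gall: Gall) -> List[Tuple[Node, ...]]:
    """All C(N+M, N) interleavings of the non-hybridizing side nodes.

    Each arrangement lists side nodes most-ancestral-first and preserves
    the within-side ancestral order.
    """
    return list(_interleavings(gall.left_side, gall.right_side))


def _row_availabilities(
    gall: Gall, subtrees: GallSubtrees, arrangement: Sequence[Node]
) -> List[Tuple[int, int]]:
    """(v, p) per assignment-matrix row, in fixed row order.

    Row order is T_l1..T_lN, T_r1..T_rM, T_L, T_R, T_C.  The subtree of
    the side node ranked k (1-based) may use periods k..N+M+1, i.e.
    p = N+M+2-k; the three bottom subtrees may use only the final period.
    """
    P = gall.N + gall.M + 1
    rank = {node: i + 1 for i, node in enumerate(arrangement)}
    rows = []
    for node, sub in zip(
        list(gall.left_side) + list(gall.right_side),
        subtrees.left_subtrees + subtrees.right_subtrees,
    ):
        rows.append((event_count(sub), P + 1 - rank[node]))
    for sub in (subtrees.L, subtrees.R, subtrees.C):
        rows.append((event_count(sub), 1))
    return rows


def enumerate_assignments(
    arrangement: Sequence[Node], gall: Gall, subtrees: GallSubtrees
) -> List[AssignmentMatrix]:
    """All assignment matrices for one side-node arrangement.

    A matrix has N+M+3 rows (subtrees, fixed order) and N+M+1 columns
    (time periods); row i sums to v(T_i) and is zero in periods not
    available to subtree i.  The number of matrices is the stars-and-bars
    product prod_i C(v_i + p_i - 1, v_i).
    """
    P = gall.N + gall.M + 1
    rows = _row_availabilities(gall, subtrees, arrangement)
    per_row: List[List[Tuple[int, ...]]] = []
    for v, p in rows:
        opts = [(0,) * (P - p) + comp for comp in weak_compositions(v, p)]
        per_row.append(opts)
    return [tuple(choice) for choice in itertools.product(*per_row)]


def assignment_weight(A: AssignmentMatrix) -> int:
    """Product over periods of the multinomial of that period's column."""
    out = 1
    for col in zip(*A):
        out *= multinomial(col)
    return out


def _arrangement_sum(rows: Sequence[Tuple[int, int]], P: int) -> int:
    """Sum of assignment weights over all assignments for fixed (v, p) rows."""
    per_row = []
    for v, p in rows:
        per_row.append([(0,) * (P - p) + comp for comp in weak_compositions(v, p)])
    total = 0
    for choice in itertools.product(*per_row):
        w = 1
        for col in zip(*choice):
            w *= multinomial(col)
        total += w
    return total


def gall_breakdown(gall: Gall, subtrees: GallSubtrees) -> List[dict]:
    """Per-arrangement assignment counts and inner sums for one gall.

    Each record has ``arrangement`` (side nodes, most ancestral first),
    ``n_assignments`` (the stars-and-bars product) and ``inner_sum`` (the
    summed multinomial weights, with subtree history counts held fixed).
    """
    P = gall.N + gall.M + 1
    out = []
    for arr in side_arrangements(gall):
        rows = _row_availabilities(gall, subtrees, arr)
        n_assign = 1
        for v, p in rows:
            n_assign *= math.comb(v + p - 1, v)
        out.append(
            {
                "arrangement": arr,
                "n_assignments": n_assign,
                "inner_sum": _arrangement_sum(rows, P),
            }
        )
    return out


def count_gall(
    gall: Gall,
    subtrees: GallSubtrees,
    subtree_counts: Optional[Sequence[int]] = None,
) -> int:
    """Labeled histories of the subtree rooted at a gall's top node.

    ``subtree_counts`` optionally supplies the history counts of the
    N+M+3 subtrees in row order (computed recursively if omitted).
    """
    if subtree_counts is None:
        subtree_counts = [count_labeled_histories(t) for t in subtrees.row_order()]
    prod = 1
    for c in subtree_counts:
        prod *= c
    inner = sum(rec["inner_sum"] for rec in gall_breakdown(gall, subtrees))
    return prod * inner


# -- main recursion --------------------------------------------------------


def count_labeled_histories(tree: GalledTree) -> int:
    """Number of labeled histories of a valid galled tree.

    Recursive from the root: an ordinary tree node interleaves its two
    subtrees; the top node of a gall is handled by the gall decomposition.
    Results are memoized across calls on the canonical form of each
    subtree, so repeated isomorphic subtrees are computed once.
    """
    validate(tree, raise_on_error=True)
    galls_by_top = {g.top: g for g in find_galls(tree)}

    def go(node: Node) -> Tuple[Shape, int, int]:
        """Returns (canonical shape, history count, event count)."""
        if tree.is_leaf(node):
            return ("L",), 1, 0
        gall = galls_by_top.get(node)
        if gall is not None:
            comp_roots = (
                [off_cycle_child(tree, gall, s) for s in gall.left_side]
                + [
                    off_cycle_child(tree, gall, gall.left_hybridizing),
                    off_cycle_child(tree, gall, gall.hybrid),
                    off_cycle_child(tree, gall, gall.right_hybridizing),
                ]
                + [
                    off_cycle_child(tree, gall, s)
                    for s in reversed(gall.right_side)
                ]
            )
            results = [go(r) for r in comp_roots]
            parts = tuple(r[0] for r in results)
            forward = ("G", gall.N, parts)
            reflected = ("G", gall.M, tuple(reversed(parts)))
            shape = min(forward, reflected)
            vs = [r[2] for r in results]
            v = gall.N + gall.M + 2 + sum(vs)
            if shape in _SHAPE_CACHE:
                return shape, _SHAPE_CACHE[shape], v
            # rows in fixed row order: side subtrees then T_L, T_R, T_C
            nl = gall.N
            left_vs = vs[:nl]  # ancestral-first
            vL, vC, vR = vs[nl], vs[nl + 1], vs[nl + 2]
            right_vs = list(reversed(vs[nl + 3 :]))  # ancestral-first
            P = gall.N + gall.M + 1
            inner = 0
            for merged in _interleavings(
                [("l", i) for i in range(len(left_vs))],
                [("r", i) for i in range(len(right_vs))],
            ):
                rows = []
                for k, (side, idx) in enumerate(merged):
                    vv = left_vs[idx] if side == "l" else right_vs[idx]
                    rows.append((vv, P - k))
                rows += [(vL, 1), (vR, 1), (vC, 1)]
                inner += _arrangement_sum(rows, P)
            lh = inner
            for r in results:
                lh *= r[1]
            _SHAPE_CACHE[shape] = lh
            return shape, lh, v
        c1, c2 = tree.children[node]
        s1, lh1, v1 = go(c1)
        s2, lh2, v2 = go(c2)
        shape = ("T", s1, s2) if s1 <= s2 else ("T", s2, s1)
        v = v1 + v2 + 1
        if shape in _SHAPE_CACHE:
            return shape, _SHAPE_CACHE[shape], v
        lh = lh1 * lh2 * math.comb(v1 + v2, v2)
        _SHAPE_CACHE[shape] = lh
        return shape, lh, v

    return go(tree.root)[1]
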