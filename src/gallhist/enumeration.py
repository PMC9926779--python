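"""Exhaustive enumeration of unlabeled galled trees.

Unlabeled galled trees are identified up to two isomorphisms: swapping the
two children of any tree node, and reflecting any gall (exchanging its left
and right sides).  With ``n`` leaves there are 1, 1, 2, 6, 20, 72 such
trees for n = 1..6, and the gall-free stratum follows the
Wedderburn-Etherington numbers 1, 1, 1, 2, 3, 6, ...

Two independent generators are provided.  The structured generator mirrors
the combinatorial scheme the counts come from: a tree either has a plain
root (an unordered pair of smaller galled trees) or a root gall, in which
case the leaves are split by an integer composition across the gall's
subtrees, with reflection handled at the composition level (keep one of
each non-palindromic pair; for palindromic compositions order the two
side-subtree lists).  The naive generator produces every ordered variant
and deduplicates by canonical form; agreement between the two is the main
guard on the dedup rules.
"""

from __future__ import annotations

import functools
import itertools
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .errors import DomainError
from .model import (
    LEAF,
    GalledTree,
    Shape,
    max_galls,
    shape_gall_count,
    shape_leaf_count,
    tree_to_shape,
)

# -- canonical forms -------------------------------------------------------


def canonical_shape(shape: Shape) -> Shape:
    """Canonicalize a shape tuple under child-swap and gall reflection."""
    if shape[0] == "L":
        return LEAF
    if shape[0] == "T":
        a = canonical_shape(shape[1])
        b = canonical_shape(shape[2])
        return ("T", a, b) if a <= b else ("T", b, a)
    n_left = shape[1]
    parts = tuple(canonical_shape(p) for p in shape[2])
    m_right = len(parts) - 3 - n_left
    forward = ("G", n_left, parts)
    reflected = ("G", m_right, tuple(reversed(parts)))
    return min(forward, reflected)


def canonical_form(tree: GalledTree) -> str:
    """A string key equal for two trees iff they are isomorphic."""
    return repr(canonical_shape(tree_to_shape(tree)))


# -- Wedderburn-Etherington ------------------------------------------------


@functools.lru_cache(maxsize=None)
def wedderburn_etherington(n: int) -> int:
    """Number of unlabeled rooted binary trees with ``n`` leaves.

    Recursion with separate even/odd cases:
    U_1 = 1;
    U_n = sum_{k=1}^{n/2-1} U_k U_{n-k} + U_{n/2}(U_{n/2}+1)/2 for even n;
    U_n = sum_{k=1}^{(n-1)/2} U_k U_{n-k} for odd n.
    """
    if n < 1:
        raise DomainError("leaf count must be at least 1")
    if n == 1:
        return 1
    if n % 2 == 0:
        half = n // 2
        total = sum(
            wedderburn_etherington(k) * wedderburn_etherington(n - k)
            for k in range(1, half)
        )
        u = wedderburn_etherington(half)
        return total + u * (u + 1) // 2
    return sum(
        wedderburn_etherington(k) * wedderburn_etherington(n - k)
        for k in range(1, (n - 1) // 2 + 1)
    )


# -- generators ------------------------------------------------------------


def _compositions(n: int, k: int) -> Iterator[Tuple[int, ...]]:
    """Compositions of n into exactly k positive parts."""
    if k == 0:
        if n == 0:
            yield ()
        return
    if k == 1:
        if n >= 1:
            yield (n,)
        return
    for first in range(1, n - k + 2):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


@functools.lru_cache(maxsize=None)
def _gallfree_shapes(n: int) -> Tuple[Shape, ...]:
    if n < 1:
        raise DomainError("leaf count must be at least 1")
    if n == 1:
        return (LEAF,)
    out = set()
    for k in range(1, n // 2 + 1):
        left = _gallfree_shapes(k)
        right = _gallfree_shapes(n - k)
        if k == n - k:
            pairs = itertools.combinations_with_replacement(sorted(left), 2)
        else:
            pairs = itertools.product(left, right)
        for a, b in pairs:
            out.add(("T", a, b) if a <= b else ("T", b, a))
    return tuple(sorted(out))


def _root_gall_shapes(n: int) -> Iterator[Shape]:
    """All canonical shapes with a gall at the root, per the composition
    scheme with n_left >= n_right and palindrome handling."""
    for n_l in range(0, n - 3 + 1):
        for n_r in range(0, n_l + 1):
            k = n_l + n_r + 3
            if k > n:
                continue
            for comp in _compositions(n, k):
                if n_l == n_r:
                    rev = tuple(reversed(comp))
                    if comp != rev:
                        # non-palindromic pair (c, c'): keep the smaller
                        if comp > rev:
                            continue
                        for parts in itertools.product(
                            *[_galled_shapes(sz) for sz in comp]
                        ):
                            yield canonical_shape(("G", n_l, parts))
                    else:
                        # palindromic composition: order the two side lists
                        side_sizes = comp[: n_l + 1]
                        side_lists = sorted(
                            itertools.product(
                                *[_galled_shapes(sz) for sz in side_sizes]
                            )
                        )
                        mid_size = comp[n_l + 1]
                        for i, a in enumerate(side_lists):
                            for b in side_lists[i:]:
                                for c in _galled_shapes(mid_size):
                                    parts = a + (c,) + tuple(reversed(b))
                                    yield canonical_shape(("G", n_l, parts))
                else:
                    for parts in itertools.product(
                        *[_galled_shapes(sz) for sz in comp]
                    ):
                        yield canonical_shape(("G", n_l, parts))


@functools.lru_cache(maxsize=None)
def _galled_shapes(n: int) -> Tuple[Shape, ...]:
    """All canonical galled-tree shapes with n leaves (structured scheme)."""
    if n < 1:
        raise DomainError("leaf count must be at least 1")
    if n == 1:
        return (LEAF,)
    out = set()
    # root is not the top node of a gall: unordered pair of smaller trees
    for k in range(1, n // 2 + 1):
        left = _galled_shapes(k)
        right = _galled_shapes(n - k)
        if k == n - k:
            pairs = itertools.combinations_with_replacement(sorted(left), 2)
        else:
            pairs = itertools.product(left, right)
        for a, b in pairs:
            out.add(("T", a, b) if a <= b else ("T", b, a))
    # root is the top node of a gall
    out.update(_root_gall_shapes(n))
    return tuple(sorted(out))


def structured_root_gall_shapes(n: int) -> List[Shape]:
    """Root-gall shapes as emitted by the composition scheme, duplicates
    included (there should be none; tests assert this)."""
    return list(_root_gall_shapes(n))


@functools.lru_cache(maxsize=None)
def _galled_shapes_naive(n: int) -> frozenset:
    """Generate-everything-and-deduplicate reference enumerator."""
    if n == 1:
        return frozenset({LEAF})
    out = set()
    for k in range(1, n):
        for a in _galled_shapes_naive(k):
            for b in _galled_shapes_naive(n - k):
                out.add(canonical_shape(("T", a, b)))
    for n_l in range(0, n - 3 + 1):
        for n_r in range(0, n - 3 - n_l + 1):
            k = n_l + n_r + 3
            for comp in _compositions(n, k):
                for parts in itertools.product(
                    *[tuple(_galled_shapes_naive(sz)) for sz in comp]
                ):
                    out.add(canonical_shape(("G", n_l, parts)))
    return frozenset(out)


def naive_galled_shapes(n: int) -> frozenset:
    return _galled_shapes_naive(n)


# -- public enumeration API ------------------------------------------------


def enumerate_gallfree(n: int) -> List[GalledTree]:
    """All unlabeled rooted binary trees with n leaves (count U_n)."""
    return [GalledTree.from_shape(s) for s in _gallfree_shapes(n)]


def enumerate_galled(n: int, g: Optional[int] = None) -> List[GalledTree]:
    """All unlabeled galled trees with n leaves (optionally exactly g galls).

    Leaves are labeled arbitrarily L1..Ln; labels never affect counts.
    """
    if g is not None and not 0 <= g <= max_galls(n):
        raise DomainError(
            f"{g} galls infeasible for {n} leaves (max {max_galls(n)})"
        )
    shapes = _galled_shapes(n)
    if g is not None:
        shapes = tuple(s for s in shapes if shape_gall_count(s) == g)
    return [GalledTree.from_shape(s) for s in shapes]


def galled_shapes(n: int, g: Optional[int] = None) -> List[Shape]:
    """Canonical shapes only (cheaper than materializing trees)."""
    shapes = _galled_shapes(n)
    if g is not None:
        shapes = tuple(s for s in shapes if shape_gall_count(s) == g)
    return list(shapes)


def max_histories_table(n: int) -> List[dict]:
    """Per-gall-count summary for n leaves: tree count and max history count.

    One record per feasible g, each with keys ``n``, ``g``, ``num_trees``,
    ``max_histories``.  Exhaustive, so intended for small n (say <= 7).
    """
    from .counting import count_labeled_histories  # local: avoid cycle

    records = []
    for g in range(0, max_galls(n) + 1):
        trees = enumerate_galled(n, g)
        counts = [count_labeled_histories(t) for t in trees]
        records.append(
            {
                "n": n,
                "g": g,
                "num_trees": len(trees),
                "max_histories": max(counts) if counts else 0,
            }
        )
    return records
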