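"""Reference trees and a seeded random galled-tree generator.

The two reference trees are small worked examples used throughout the
documentation and tests:

* :func:`single_gall_example` — 11 leaves (A..K), one gall with one left
  and two right non-hybridizing side nodes and a cherry under the hybrid
  node; a convenient exhibit of gall anatomy and the display numbering.
* :func:`three_gall_example` — 17 leaves, three galls (one at the root,
  one inside the left hybridizing subtree, one inside a side-node
  subtree); its count of 23,783,760 labeled histories exercises every
  piece of the gall decomposition.

The random generator draws a valid galled tree with an exact leaf and
gall count.  It builds top-down — choosing at each step whether the root
of the remaining subproblem is a gall top, then splitting leaves and the
remaining gall budget uniformly over feasible options — so it is simple
and reproducible rather than uniform over shapes; it exists to feed
property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional

from .errors import InfeasibleError
from .model import LEAF, GalledTree, Shape, max_galls
from .newick_io import parse_enewick

__all__ = [
    "SINGLE_GALL_EXAMPLE",
    "THREE_GALL_EXAMPLE",
    "single_gall_example",
    "three_gall_example",
    "wide_gall_family",
    "GeneratorConfig",
    "random_galled_tree",
]

SINGLE_GALL_EXAMPLE = "((((A,B),E),(F,((C,D))#H1)),(((#H1,(G,H)),(I,J)),K));"

THREE_GALL_EXAMPLE = (
    "((((a,b),c),(((d,(e)#H2),(#H2,f)),((g,h))#H1)),"
    "((((m,(n)#H3),(#H3,o)),(p,q)),(#H1,((i,j),(k,l)))));"
)


def single_gall_example() -> GalledTree:
    """11-leaf tree with one gall (N=1 left, M=2 right side nodes)."""
    return parse_enewick(SINGLE_GALL_EXAMPLE)


def three_gall_example() -> GalledTree:
    """17-leaf, three-gall tree with 23,783,760 labeled histories."""
    return parse_enewick(THREE_GALL_EXAMPLE)


def wide_gall_family(k: int) -> GalledTree:
    """Root gall with k non-hybridizing side nodes per side, each bearing a
    cherry; hybridizing nodes and the hybrid node bear single leaves.

    The side-node arrangements of the root gall number C(2k, k), growing
    as 4^k / sqrt(pi k), which is what makes wide galls the expensive case
    for the counting recursion.
    """
    if k < 0:
        raise InfeasibleError("k must be >= 0")
    cherry: Shape = ("T", LEAF, LEAF)
    parts = (cherry,) * k + (LEAF, LEAF, LEAF) + (cherry,) * k
    return GalledTree.from_shape(("G", k, parts))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for :func:`random_galled_tree`.

    ``max_side_nodes`` caps the non-hybridizing side nodes per gall side,
    keeping generated galls from swallowing the whole leaf budget.
    """

    n: int
    g: int
    seed: int
    max_side_nodes: int = 3


def _capacity(n: int) -> int:
    return (n - 1) // 2 if n >= 1 else 0


def _random_shape(rng: random.Random, n: int, g: int, max_side: int) -> Shape:
    if n == 1:
        return LEAF
    options: List[tuple] = []
    for n1 in range(1, n):
        n2 = n - n1
        for g1 in range(0, g + 1):
            if g1 <= _capacity(n1) and g - g1 <= _capacity(n2):
                options.append(("T", n1, g1))
    if g > 0:
        for n_l in range(0, max_side + 1):
            for n_r in range(0, max_side + 1):
                k = n_l + n_r + 3
                # max achievable sub-gall capacity over compositions of n
                # into k parts is (n - k) // 2
                if k <= n and g - 1 <= (n - k) // 2:
                    options.append(("G", n_l, n_r))
    if not options:
        raise InfeasibleError(f"no feasible construction for n={n}, g={g}")
    pick = options[rng.randrange(len(options))]
    if pick[0] == "T":
        _, n1, g1 = pick
        return (
            "T",
            _random_shape(rng, n1, g1, max_side),
            _random_shape(rng, n - n1, g - g1, max_side),
        )
    _, n_l, n_r = pick
    k = n_l + n_r + 3
    while True:
        parts = [1] * k
        for _ in range(n - k):
            parts[rng.randrange(k)] += 1
        if sum(_capacity(p) for p in parts) >= g - 1:
            break
    part_galls = [0] * k
    for _ in range(g - 1):
        candidates = [
            i for i in range(k) if part_galls[i] + 1 <= _capacity(parts[i])
        ]
        part_galls[candidates[rng.randrange(len(candidates))]] += 1
    sub = tuple(
        _random_shape(rng, parts[i], part_galls[i], max_side) for i in range(k)
    )
    return ("G", n_l, sub)


def random_galled_tree(
    config: Optional[GeneratorConfig] = None,
    *,
    n: Optional[int] = None,
    g: Optional[int] = None,
    seed: Optional[int] = None,
    max_side_nodes: int = 3,
) -> GalledTree:
    """Draw a valid galled tree with exactly n leaves and g galls.

    Deterministic for a fixed config.  Raises
    :class:`InfeasibleError` when n < 2g + 1.
    """
    if config is None:
        config = GeneratorConfig(n, g, seed, max_side_nodes)
    if config.n < 1:
        raise InfeasibleError("need at least one leaf")
    if config.n < 2 * config.g + 1:
        raise InfeasibleError(
            f"{config.g} galls need at least {2 * config.g + 1} leaves; got {config.n}"
        )
    rng = random.Random(config.seed)
    shape = _random_shape(rng, config.n, config.g, config.max_side_nodes)
    return GalledTree.from_shape(shape)
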