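"""Brute-force verification via linear extensions of the event poset.

A labeled history is exactly a linear extension of the partial order on
*events* obtained by contracting each hybridization triple (hybrid node
plus its two parents, which are simultaneous) to a single element and
keeping the ancestor-descendant relations.  Counting linear extensions by
dynamic programming over downsets is independent of the recursive gall
decomposition in :mod:`gallhist.counting`, so agreement between the two is
a strong correctness check.

The downset DP is exponential in the worst case (#P-hard in general); the
default state limit keeps it to posets whose ideal lattice is modest,
which covers every event poset used in the test suite (up to ~16 events).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx

from .errors import SizeLimitError, TemporallyInconsistentError
from .model import GalledTree, LabeledHistory, event_graph, validate

__all__ = [
    "EventPoset",
    "build_event_poset",
    "count_linear_extensions",
    "enumerate_labeled_histories",
]

DEFAULT_STATE_LIMIT = 10**6


@dataclass
class EventPoset:
    """Events of a galled tree under the ancestry partial order.

    ``events[i]`` is the frozenset of tree nodes making up event i (a
    singleton coalescence or a hybridization triple).  ``preds[i]`` is the
    bitmask of events that must precede event i (immediate generators;
    their transitive closure is implied by downset construction).
    """

    events: List[frozenset]
    preds: List[int]

    @property
    def size(self) -> int:
        return len(self.events)


def build_event_poset(tree: GalledTree) -> EventPoset:
    """Contract hybridization triples and restrict ancestry to events.

    Raises :class:`TemporallyInconsistentError` if contraction creates a
    cycle (the disallowed temporal impossibilities are exactly such
    cycles).  Leaves are excluded; they form the final simultaneity set of
    every labeled history by construction.
    """
    eg, event_of = event_graph(tree)
    if not nx.is_directed_acyclic_graph(eg):
        raise TemporallyInconsistentError(
            "hybridization contraction creates a cycle among events"
        )
    members: Dict[tuple, set] = {e: set() for e in eg.nodes}
    for node, e in event_of.items():
        members[e].add(node)
    keys = list(eg.nodes)
    index = {e: i for i, e in enumerate(keys)}
    preds = [0] * len(keys)
    for u, v in eg.edges:
        preds[index[v]] |= 1 << index[u]
    return EventPoset([frozenset(members[e]) for e in keys], preds)


def count_linear_extensions(
    poset: EventPoset, state_limit: int = DEFAULT_STATE_LIMIT
) -> int:
    """Exact number of total orders extending the event poset.

    Dynamic programming over downsets (order ideals): the number of ways
    to complete a downset is summed over its addable elements.  Raises
    :class:`SizeLimitError` if the number of distinct downsets visited
    exceeds ``state_limit``.
    """
    m = poset.size
    full = (1 << m) - 1
    memo: Dict[int, int] = {full: 1}

    def f(mask: int) -> int:
        if mask in memo:
            return memo[mask]
        if len(memo) > state_limit:
            raise SizeLimitError(
                f"downset lattice exceeds {state_limit} states; raise "
                "state_limit to proceed"
            )
        total = 0
        for i in range(m):
            bit = 1 << i
            if not mask & bit and (poset.preds[i] & mask) == poset.preds[i]:
                total += f(mask | bit)
        memo[mask] = total
        return total

    return f(0)


def enumerate_labeled_histories(
    tree: GalledTree, limit: int = 10_000
) -> List[LabeledHistory]:
    """Explicitly list all labeled histories of *tree* (count <= limit).

    Each history is the root set, one set per event in extension order
    (hybridization triples stay together), and the leaf set last.
    """
    validate(tree, raise_on_error=True)
    poset = build_event_poset(tree)
    total = count_linear_extensions(poset)
    if total > limit:
        raise SizeLimitError(
            f"{total} labeled histories exceed the requested limit {limit}"
        )
    m = poset.size
    leaves = frozenset(tree.leaves)
    out: List[LabeledHistory] = []
    order: List[int] = []

    def dfs(mask: int) -> None:
        if len(order) == m:
            ranking = [frozenset(poset.events[i]) for i in order]
            out.append(LabeledHistory(ranking + [leaves]))
            return
        for i in range(m):
            bit = 1 << i
            if not mask & bit and (poset.preds[i] & mask) == poset.preds[i]:
                order.append(i)
                dfs(mask | bit)
                order.pop()

    dfs(0)
    return out
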