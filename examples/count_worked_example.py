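"""Count labeled histories of the 17-leaf, three-gall reference tree.

Walks through the gall decomposition at the root: the subtree history
counts, the per-arrangement assignment counts and inner sums, and the
final total.
"""

import math

from gallhist import (
    count_labeled_histories,
    event_count,
    find_galls,
    gall_breakdown,
    gall_subtrees,
    three_gall_example,
)

tree = three_gall_example()
print(f"tree: {tree.n} leaves, {tree.g} galls, {event_count(tree)} events")

root_gall = next(g for g in find_galls(tree) if g.top == tree.root)
sub = gall_subtrees(tree, root_gall)
names = (
    [f"T_l{i+1}" for i in range(root_gall.N)]
    + [f"T_r{i+1}" for i in range(root_gall.M)]
    + ["T_L", "T_R", "T_C"]
)
counts = [count_labeled_histories(t) for t in sub.row_order()]
for name, t, c in zip(names, sub.row_order(), counts):
    print(f"  {name}: {t.n} leaves, {event_count(t)} events, {c} histories")
print(f"product of subtree history counts: {math.prod(counts)}")

inner_total = 0
for rec in gall_breakdown(root_gall, sub):
    side = "right" if rec["arrangement"][0] in root_gall.right_side else "left"
    print(
        f"arrangement ({side} side node first): "
        f"{rec['n_assignments']} assignments, inner sum {rec['inner_sum']:,}"
    )
    inner_total += rec["inner_sum"]

total = count_labeled_histories(tree)
print(f"total labeled histories: {math.prod(counts)} x {inner_total:,} = {total:,}")
# The total is the number of distinct temporal orderings of the tree's 16
# events (each hybridization counting as one simultaneous triple).
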