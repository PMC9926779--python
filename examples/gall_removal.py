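"""Remove galls one by one and watch the history count grow.

Deleting a gall's hybrid node and one hybridizing side node (rejoining
the severed edges) keeps the leaf set and maps every labeled history of
the original tree to one of the result, so the count never decreases.
"""

from gallhist import (
    count_labeled_histories,
    find_galls,
    remove_gall,
    three_gall_example,
    write_enewick,
)

tree = three_gall_example()
while True:
    print(
        f"g={tree.g}: {count_labeled_histories(tree):,} labeled histories"
    )
    galls = find_galls(tree)
    if not galls:
        break
    tree = remove_gall(tree, galls[0], side="right")
print("final gall-free tree:")
print(write_enewick(tree))
# Each removal relaxes the simultaneity constraint of one hybridization,
# so the count is monotone along the sequence.
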