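# Methods

## Model and assumptions

The objects are rooted binary galled trees: directed acyclic graphs with a
unique root (in-degree 0, out-degree 2; out-degree 0 only for the one-leaf
tree), leaves of degree (1, 0), and internal nodes of degree (1, 2) (tree
nodes) or (2, 1) (reticulation/hybrid nodes). Every hybrid node `a` has a
unique ancestor `r` (the gall's *top node*) joined to `a` by exactly two
node-disjoint directed paths; the resulting undirected cycles are pairwise
vertex-disjoint and non-nested. Branch lengths are outside the model; only
topology and temporal order matter.

Time runs from the root toward the contemporaneous leaves. A hybrid node and
its two parents are simultaneous, so each hybridization is one *event*;
every other internal tree node is a coalescence event. Consequently a galled
tree with `n` leaves and `g` galls has `n − 1 + 2g` internal nodes but
always exactly `n − 1` events, and a labeled history is a sequence of `n`
simultaneity sets: the root, one set per event, and finally the leaves. The
feasibility bound `g ≤ ⌊(n − 1)/2⌋` follows because the minimal gall has
three leaves and each further gall adds at least two.

Left/right orientation of a gall's sides is stored (it follows the child
order of the input) but is *non-semantic*: every computation is invariant
under swapping the children of any tree node and under reflecting any gall,
and the test suite asserts this. The display numbering
(`postorder_numbering`) that places child nodes before parents and numbers
a hybrid's subtree first within its gall is a drawing convention only.

## Counting

`count_labeled_histories` recurses from the root. At an ordinary tree node
the two subtree histories are interleaved:
`L_H = L_H(T_l) L_H(T_r) C(v_l + v_r, v_r)`. At a gall top with `N` left
and `M` right non-hybridizing side nodes the gall is decomposed into its
`N + M + 3` subtrees and

1. the side nodes are interleaved (`C(N+M, N)` arrangements, each defining
   `N + M + 1` time periods — between consecutive ranked side nodes, then
   between the last side node and the hybridization, then below it);
2. per arrangement, each subtree's events are assigned to its available
   periods — the subtree of the side node ranked `k` may use periods
   `k..N+M+1` (so `p = N + M + 2 − k`), and the subtrees of the two
   hybridizing nodes and the hybrid node only the final period;
3. each assignment matrix (rows: subtrees in the fixed order
   `T_l1..T_lN, T_r1..T_rM, T_L, T_R, T_C`; columns: periods) is weighted
   by the product over columns of the multinomial coefficient of the
   column;
4. the summed weights, totaled over arrangements, multiply the product of
   the subtree history counts.

The row order is a package convention — the weight is symmetric in rows, so
any fixed order is equivalent. The gall's own events (top node, side nodes,
hybridization) are never placed in an assignment matrix; they are accounted
for when the gall-rooted subtree is interleaved higher up, via its event
count `v = N + M + 2 + Σ v(T_i)`.

Assignment sets are enumerated naively as Cartesian products of weak
compositions. This matches the structure of the method and is exact; the
stars-and-bars cardinality `∏ C(v_i + p_i − 1, v_i)` is asserted against
the explicit generation. All arithmetic uses Python's arbitrary-precision
integers; there is no floating point anywhere in a count. Results are
memoized on the canonical form of each subtree, which matters when
tabulating all small trees (isomorphic subtrees recur constantly).

Wide galls are the expensive case: a root gall with `k` non-hybridizing
side nodes per side already requires summing over `C(2k, k)` arrangements
(`fixtures.wide_gall_family` builds this family; with cherries on the side
nodes and single leaves below the hybridizing and hybrid nodes it has
`4k + 3` leaves). The per-side cap in the random generator
(`max_side_nodes`, default 3) keeps property-test inputs away from this
blow-up.

## Oracle

`oracle.build_event_poset` contracts each hybridization triple to a single
element and restricts the ancestry order to events; leaves are dropped
(they form the final set of every history by construction). Labeled
histories are exactly the linear extensions of this poset, which
`count_linear_extensions` counts by dynamic programming over downsets
(memoized on a bitmask frontier). The DP is exponential in the worst case —
general linear-extension counting is #P-hard — so a configurable state
limit (default 10⁶ downsets) aborts cleanly on oversized inputs; every
poset used in the tests (≤ 16 events) stays far below it. The oracle shares
nothing with the recursive counter beyond the tree container, which is what
makes the equivalence tests informative.

`enumerate_labeled_histories` materializes the extensions explicitly (with
a count-based guard) and each emitted history is re-validated against the
definition: `n` sets, root first, leaves last, hybridizations as intact
triples, ancestry respected.

## Enumeration

Unlabeled galled trees are identified up to child swap and gall reflection;
`canonical_form` computes a key by recursively sorting child keys and
taking the lexicographic minimum of each gall's subtree sequence and its
reversal. That reflection is an isomorphism of unlabeled galled trees is a
modeling choice (the alternative would distinguish mirror-image galls); it
is what makes the small-tree totals 1, 1, 2, 6, 20, 72 and is applied
consistently everywhere.

The structured enumerator builds trees with `n` leaves two ways: root not a
gall top (unordered pairs of smaller galled trees, with
combinations-with-replacement when the halves have equal size) and root a
gall top. For the latter it fixes side-node counts `n_l ≥ n_r`, splits the
leaves by an integer composition across the `n_l + n_r + 3` subtrees
(composition order: most ancestral left side node → left hybridizing →
hybrid → right hybridizing → … → most ancestral right side node), and fills
each part with every smaller galled tree. Reflection is quotiented at the
composition level: for `n_l = n_r`, one of each non-palindromic pair
`(c, c′)` is kept (the lexicographically smaller — any fixed choice works),
and for palindromic compositions the two side-subtree lists are drawn as an
unordered pair with replacement, ordered by the canonical key. A naive
enumerator (generate every ordered variant, deduplicate by canonical form)
is kept alongside, and the two are asserted equal for all n ≤ 6; this dual
route is the guard on the dedup rules, and the structured emitter is also
asserted duplicate-free.

Per-gall-count summaries (`max_histories_table`) recompute tree counts and
maximum history counts exhaustively; the observation that the per-`n`
maximum is always attained by a gall-free tree follows from the
gall-removal argument below and is asserted for n ≤ 6.

## Gall removal

`remove_gall` deletes the hybrid node and one hybridizing side node
(default the right one; both sides are exposed and tested), then joins the
surviving hybridizing node to the hybrid's child and the deleted node's
parent to its remaining child. The leaf set is preserved and the gall count
drops by one. Every labeled history of the input maps injectively to one of
the output — the hybridization set is replaced by the surviving hybridizing
node alone — so the history count never decreases; the suite checks this
exhaustively for n ≤ 6 and on random trees to n = 9.

## Fixtures and the random generator

The 17-leaf three-gall reference tree exercises every code path: a root
gall with one side node per side, a nested gall inside a hybridizing
subtree, and a gall inside a side-node subtree. The 11-leaf single-gall
tree exhibits the anatomy and display numbering. Both are stored as
eNewick strings and parsed (and so validated) on access. In the 11-leaf
tree, only part of the structure is pinned down by its documented
properties (gall with N=1/M=2, a cherry under the hybrid node, the display
numbering, and a specific valid event sequence); the remaining leaf
placement was fixed once, consistently with all of those.

The random generator draws shapes top-down: at each subproblem it picks
uniformly among the feasible constructions (tree-node splits of the leaf
and gall budgets, or a root gall with bounded side-node counts), then
splits leaves and galls feasibly at random. It is deterministic for a
fixed seed, guarantees the exact leaf and gall counts, and makes no
uniformity claim over shapes — a coverage smoke test asserts only that
2,000 draws reach every shape with n ≤ 5. Real phylogenetic networks have
branch lengths, non-binary nodes, and non-gall reticulations; none of
those are modeled, so passing property tests says nothing beyond the
combinatorial model above.

## Extended Newick

Reticulations are written with `#H<k>` tags, each appearing exactly twice:
once carrying the hybrid's subtree (under either parent on input; under
the canonically first parent on output) and once as a bare reference.
Branch lengths are parsed and discarded with a warning; duplicate leaf
labels are a hard error. The writer is canonical — children ordered by
canonical key (ties broken by leaf labels), galls oriented by their
canonical reflection — so it is deterministic and the identity on its own
output, and parse∘write always reproduces the input up to isomorphism.
The parser and writer are implemented here because mainstream tree
libraries do not represent reticulation tags.

## Degenerate and invalid inputs

Validation reports the first violated condition with a stable code:
`NOT_ROOTED_DAG`, `DEGREE_VIOLATION`, `NESTED_CYCLES` (a top-to-hybrid
walk meets another reticulation), `SHARED_CYCLE_VERTICES` (two galls
overlap), `TEMPORALLY_INCONSISTENT` (event contraction creates a cycle).
A "gall" whose top node is itself a parent of its hybrid is rejected as a
degree problem: the decomposition requires every hybridizing node to carry
an off-cycle subtree, i.e. every gall has at least three subtrees. In
exhaustive and randomized testing the temporal check never fired on inputs
passing the disjointness checks — for vertex-disjoint, non-nested galls a
time function appears always to exist, the impossibilities being caught
earlier as shared or nested cycles — but the check is kept as a guard.
The single-leaf tree is a valid galled tree with one history, and serves
as the recursion's base case (`v = 0`, `L_H = 1`).

## Problem sizes

Exhaustive checks run over all 102 unlabeled galled trees with n ≤ 6 plus
enumerations to n = 8 in the gall-free stratum; randomized equivalence
checks use 200 trees with n ≤ 8 and structural checks 1,000 draws with
n ≤ 10. These sizes keep the full suite to a few seconds while covering
every branch of the decomposition (the counter itself handles much larger
trees; cost is driven by gall width, not leaf count).
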