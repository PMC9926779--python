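# gallhist

Exact counting of **labeled histories** for rooted binary **galled trees**.

A labeled topology — a leaf-labeled rooted binary tree or network — is
compatible with one or more *labeled histories*: total temporal orderings of
its branching events, viewed with time running from the root to the
contemporaneous leaves. For trees, the number of labeled histories is a
classical quantity used throughout coalescent theory and phylogenetic
combinatorics. This package extends the computation to **galled trees**:
rooted binary phylogenetic networks whose reticulation cycles (*galls*) are
vertex-disjoint and non-nested, a subclass of tree-child networks. Each
hybrid node is treated as simultaneous with its two parents, so a
hybridization is a single event and a galled tree with *n* leaves always has
exactly *n − 1* events.

It is intended for researchers in mathematical phylogenetics and coalescent
theory who need exact ranked-network counts, reference enumerations of small
galled trees, or a verified starting point for further combinatorics on
ranked networks.

## The computation

For a gall-free (sub)tree with *n* leaves the count is classical:

```
L_H(T) = L_H(T_l) · L_H(T_r) · C(v(T_l) + v(T_r), v(T_r))        (recursion)
L_H(T) = (n − 1)! / ∏_{i internal} v(T_i)                        (closed form)
```

where `v(T)` is the number of events of `T`. When the root of a subtree is
the **top node of a gall** with `N` left and `M` right non-hybridizing side
nodes, the count decomposes over the gall's `N + M + 3` subtrees:

1. interleave the left and right side nodes — `C(N+M, N)` arrangements, each
   creating `N + M + 1` time periods;
2. for each arrangement, assign each subtree's events to the periods at or
   below its side node (`C(v + p − 1, v)` weak compositions per subtree);
3. weight each assignment by the product over periods of the multinomial
   coefficient of that period's event counts;
4. multiply the summed weights by the product of the subtree history counts.

All arithmetic is exact arbitrary-precision integer. An independent
brute-force oracle counts the same quantity as linear extensions of the
event poset (hybridization triples contracted) by dynamic programming over
downsets; agreement between the two routes on every enumerated small tree
and on hundreds of random trees is the package's primary correctness
evidence.

The package also enumerates **all unlabeled galled trees** with a given leaf
count (1, 1, 2, 6, 20, 72 for n = 1..6; the gall-free stratum follows the
Wedderburn–Etherington numbers), reads and writes extended Newick with
`#H` reticulation tags, and implements the gall-removal transform, which
never decreases the history count.

## Worked example

`examples/count_worked_example.py` counts the 17-leaf, three-gall reference
tree and prints every intermediate of the root-gall decomposition:

```
tree: 17 leaves, 3 galls, 16 events
  T_l1: 3 leaves, 2 events, 1 histories
  T_r1: 5 leaves, 4 events, 3 histories
  T_L: 3 leaves, 2 events, 1 histories
  T_R: 4 leaves, 3 events, 2 histories
  T_C: 2 leaves, 1 events, 1 histories
product of subtree history counts: 6
arrangement (left side node first): 30 assignments, inner sum 1,801,800
arrangement (right side node first): 45 assignments, inner sum 2,162,160
total labeled histories: 6 x 3,963,960 = 23,783,760
```

The root gall has one non-hybridizing side node per side, so there are
`C(2,1) = 2` arrangements. With the right side node more ancestral, the five
subtrees (events 2, 4, 2, 3, 1) can be dropped into the three time periods
in 45 ways; summing the multinomial weights over those 45 assignments gives
2,162,160 interleavings, and 1,801,800 for the other arrangement. Multiplied
by the 6 ways of choosing the subtrees' own histories, the tree admits
23,783,760 labeled histories — distinct temporal orderings of its 16 events.

The same numbers are available from the shell:

```
gallhist fixtures --name three-gall > t.nwk
gallhist count t.nwk            # 23783760
gallhist oracle t.nwk           # 23783760 (brute force)
gallhist count t.nwk --trace    # per-arrangement breakdown as JSON
```

Other entry points: `gallhist enumerate -n 6` (all 72 six-leaf galled
trees as eNewick), `gallhist tables -n 6` (per-tree counts plus a
per-gall-count summary), `gallhist strip-gall`, `gallhist random`.

## Layout

- `src/gallhist/model.py` — the `GalledTree` container, validation, gall
  anatomy, subtree extraction
- `src/gallhist/counting.py` — the gall-decomposition counter and the
  classical tree formulas
- `src/gallhist/oracle.py` — event poset and linear-extension brute force
- `src/gallhist/enumeration.py` — unlabeled galled-tree enumeration and
  canonical forms
- `src/gallhist/newick_io.py` — extended-Newick parsing and writing
- `src/gallhist/transforms.py`, `src/gallhist/fixtures.py` — gall removal,
  reference trees, seeded random generator
- `docs/methods.md` — model assumptions, algorithmic choices, limitations
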