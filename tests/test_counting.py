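"""Counting labeled histories: classical formulas and the gall decomposition."""

import math

import pytest

from gallhist import (
    GalledTree,
    assignment_weight,
    count_gall,
    count_labeled_histories,
    count_tree_closed,
    count_tree_recursive,
    enumerate_assignments,
    event_count,
    find_galls,
    gall_breakdown,
    gall_subtrees,
    parse_enewick,
    random_galled_tree,
    side_arrangements,
    wide_gall_family,
)
from gallhist.counting import multinomial, weak_compositions
from gallhist.errors import HasGallsError
from gallhist.model import LEAF


def _root_gall(tree):
    return next(g for g in find_galls(tree) if g.top == tree.root)


# -- classical tree formulas ----------------------------------------------


def test_caterpillar_has_one_history():
    cat = parse_enewick("(((((a,b),c),d),e),f);")
    assert count_tree_closed(cat) == 1
    assert count_labeled_histories(cat) == 1


def test_balanced_four_leaf_tree():
    bal = parse_enewick("((a,b),(c,d));")
    assert count_tree_closed(bal) == 2
    assert count_labeled_histories(bal) == 2


def test_closed_form_six_leaf_example():
    # balanced 4-leaf joined with a cherry: 5!/(5*3*1*1*1) = 8
    tree = parse_enewick("(((a,b),(c,d)),(e,f));")
    assert count_tree_closed(tree) == 8


def test_closed_form_requires_gallfree(three_gall):
    with pytest.raises(HasGallsError):
        count_tree_closed(three_gall)


def test_recursive_combination():
    cherry = parse_enewick("(a,b);")
    cherry2 = parse_enewick("(c,d);")
    assert count_tree_recursive(cherry, cherry2) == 2  # C(2,1)


@pytest.mark.parametrize("seed", range(60))
def test_recursive_equals_closed_on_random_gallfree(seed):
    n = 3 + seed % 8  # up to 10 leaves
    tree = random_galled_tree(n=n, g=0, seed=seed)
    assert count_labeled_histories(tree) == count_tree_closed(tree)


# -- gall machinery --------------------------------------------------------


def test_side_arrangements_cardinality(three_gall):
    gall = _root_gall(three_gall)
    arrs = side_arrangements(gall)
    assert len(arrs) == 2  # C(1+1, 1)
    assert {a[0] for a in arrs} == {gall.left_side[0], gall.right_side[0]}


def test_side_arrangements_trivial_and_larger():
    minimal = parse_enewick("((d,(e)#H2),(#H2,f));")
    (gall,) = find_galls(minimal)
    assert side_arrangements(gall) == [()]
    fam = find_galls(wide_gall_family(3))[0]
    arrs = side_arrangements(fam)
    assert len(arrs) == math.comb(6, 3) == 20
    assert len(set(arrs)) == 20


@pytest.mark.parametrize("k", range(0, 7))
def test_wide_gall_family_arrangement_count(k):
    """For a root gall with k side nodes per side, |S_v| = C(2k, k)."""
    gall = find_galls(wide_gall_family(k))[0]
    assert len(side_arrangements(gall)) == math.comb(2 * k, k)


def test_assignment_counts_match_stars_and_bars(three_gall):
    gall = _root_gall(three_gall)
    sub = gall_subtrees(three_gall, gall)
    by_first = {}
    for arr in side_arrangements(gall):
        matrices = enumerate_assignments(arr, gall, sub)
        by_first[arr[0]] = matrices
        # every matrix row sums to its subtree's event count
        for mat in matrices:
            for row, t in zip(mat, sub.row_order()):
                assert sum(row) == event_count(t)
    # right side node first: periods (2,1,1,1,3) over events (2,2,1,3,4) -> 45
    assert len(by_first[gall.right_side[0]]) == 45
    # left side node first -> 30
    assert len(by_first[gall.left_side[0]]) == 30


def test_assignment_weight_worked_example():
    # rows: T_l1, T_r1, T_L, T_R, T_C; one event each from T_l1 and T_r1
    # in the middle period, the rest in the final period
    A = (
        (0, 1, 1),
        (0, 1, 3),
        (0, 0, 2),
        (0, 0, 3),
        (0, 0, 1),
    )
    assert assignment_weight(A) == 2 * 50_400 == 100_800


def test_assignment_weight_trivial_and_single_column():
    assert assignment_weight(((0,), (0,), (0,))) == 1
    # all 12 events in one period: 12!/(2!2!1!3!4!)
    A = ((2,), (2,), (1,), (3,), (4,))
    assert assignment_weight(A) == 831_600


def test_gall_breakdown_inner_sums(three_gall):
    gall = _root_gall(three_gall)
    sub = gall_subtrees(three_gall, gall)
    sums = {}
    for rec in gall_breakdown(gall, sub):
        first = rec["arrangement"][0]
        side = "right" if first in gall.right_side else "left"
        sums[side] = rec
    assert sums["right"]["inner_sum"] == 2_162_160
    assert sums["right"]["n_assignments"] == 45
    assert sums["left"]["inner_sum"] == 1_801_800
    assert sums["left"]["n_assignments"] == 30


def test_count_gall_combines_subtree_counts(three_gall):
    gall = _root_gall(three_gall)
    sub = gall_subtrees(three_gall, gall)
    counts = [count_labeled_histories(t) for t in sub.row_order()]
    assert math.prod(counts) == 6
    assert count_gall(gall, sub, counts) == 6 * (2_162_160 + 1_801_800)
    assert count_gall(gall, sub) == 23_783_760


def test_minimal_gall_has_one_history():
    tree = parse_enewick("((d,(e)#H2),(#H2,f));")
    assert count_labeled_histories(tree) == 1


def test_right_side_node_subtree_has_three_histories(three_gall):
    gall = _root_gall(three_gall)
    sub = gall_subtrees(three_gall, gall)
    (t_r1,) = sub.right_subtrees
    assert t_r1.n == 5
    assert count_labeled_histories(t_r1) == 3


def test_worked_example_total(three_gall):
    assert count_labeled_histories(three_gall) == 23_783_760


def test_count_invariant_under_child_swap_and_reflection(three_gall):
    # swapping the two children of the root must not change the count
    swapped = {
        u: (tuple(reversed(cs)) if u == three_gall.root else cs)
        for u, cs in three_gall.children.items()
    }
    mirrored = GalledTree(swapped, three_gall.root, three_gall.leaf_labels)
    assert count_labeled_histories(mirrored) == 23_783_760
    # reflecting every node
    full = {u: tuple(reversed(cs)) for u, cs in three_gall.children.items()}
    assert (
        count_labeled_histories(
            GalledTree(full, three_gall.root, three_gall.leaf_labels)
        )
        == 23_783_760
    )


# -- helpers ---------------------------------------------------------------


def test_multinomial_and_weak_compositions():
    assert multinomial((1, 2, 1, 3, 3)) == 50_400
    assert multinomial(()) == 1
    comps = list(weak_compositions(4, 3))
    assert len(comps) == math.comb(4 + 3 - 1, 4)
    assert all(sum(c) == 4 for c in comps)
    assert len(set(comps)) == len(comps)
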