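"""Structural model: validation, gall anatomy, event accounting."""

import pytest

from gallhist import (
    GalledTree,
    event_count,
    find_galls,
    gall_subtrees,
    postorder_numbering,
    random_galled_tree,
    validate,
)
from gallhist.errors import InfeasibleError
from gallhist.model import max_galls, off_cycle_child


def test_reference_trees_validate(single_gall, three_gall):
    assert validate(single_gall).ok
    assert validate(three_gall).ok


def test_single_leaf_is_valid():
    tree = GalledTree({1: []}, 1, {1: "a"})
    assert validate(tree).ok
    assert tree.n == 1 and tree.g == 0
    assert event_count(tree) == 0


def test_shared_cycle_vertices_rejected():
    # two hybrid nodes with the same pair of parents: their cycles share
    # the top node and both side paths
    children = {1: [2, 3], 2: [4, 5], 3: [4, 5], 4: [6], 5: [7]}
    tree = GalledTree(children, 1, {6: "u", 7: "w"})
    report = validate(tree)
    assert not report.ok
    assert report.code == "SHARED_CYCLE_VERTICES"


def test_nested_cycles_rejected():
    # the path from one hybrid's parent to the gall top runs through a
    # second reticulation node: nested cycles
    children = {
        1: [2, 3],  # root
        2: [10, 4],  # left: leaf x, then hybrid h2
        3: [4, 5],  # right: hybrid h2, then node c
        4: [6],  # h2 -> d
        6: [11, 7],  # d: leaf e, hybrid h1
        5: [7, 12],  # c: hybrid h1, leaf y
        7: [13],  # h1 -> z
    }
    tree = GalledTree(children, 1, {10: "x", 11: "e", 12: "y", 13: "z"})
    report = validate(tree)
    assert not report.ok
    assert report.code == "NESTED_CYCLES"


def test_degree_violation_rejected():
    # internal node with three children
    children = {1: [2, 3, 4]}
    tree = GalledTree(children, 1, {2: "a", 3: "b", 4: "c"})
    report = validate(tree)
    assert not report.ok
    assert report.code == "DEGREE_VIOLATION"


def test_unreachable_node_rejected():
    children = {1: [2, 3], 4: []}
    tree = GalledTree(children, 1, {2: "a", 3: "b", 4: "stray"})
    report = validate(tree)
    assert not report.ok
    assert report.code == "NOT_ROOTED_DAG"


def test_gall_anatomy_of_single_gall_example(single_gall):
    (gall,) = find_galls(single_gall)
    assert gall.N == 1  # one left non-hybridizing side node
    assert gall.M == 2  # two right non-hybridizing side nodes
    sub = gall_subtrees(single_gall, gall)
    assert sorted(sub.C.leaf_labels.values()) == ["C", "D"]


def test_three_gall_example_has_three_galls(three_gall):
    assert len(find_galls(three_gall)) == 3


def test_gallfree_tree_has_no_galls():
    tree = GalledTree({1: [2, 3]}, 1, {2: "a", 3: "b"})
    assert find_galls(tree) == []


def test_event_counts(single_gall, three_gall):
    # 11 leaves, 12 internal nodes, 1 hybridization -> 10 events
    assert event_count(single_gall) == 10
    assert event_count(three_gall) == 16
    cherry = GalledTree({1: [2, 3]}, 1, {2: "a", 3: "b"})
    assert event_count(cherry) == 1


def test_root_gall_subtree_decomposition(three_gall):
    root_gall = next(g for g in find_galls(three_gall) if g.top == three_gall.root)
    sub = gall_subtrees(three_gall, root_gall)
    # composition order: T_l1, T_L, T_C, T_R, T_r1
    leaf_counts = [t.n for t in sub.composition_order()]
    assert leaf_counts == [3, 3, 2, 4, 5]
    assert sub.leaf_total == 17
    events = [event_count(t) for t in sub.composition_order()]
    assert events == [2, 2, 1, 3, 4]


def test_minimal_gall_decomposes_into_three_leaves():
    from gallhist import parse_enewick

    tree = parse_enewick("((d,(e)#H2),(#H2,f));")
    (gall,) = find_galls(tree)
    assert gall.N == gall.M == 0
    sub = gall_subtrees(tree, gall)
    assert [t.n for t in sub.row_order()] == [1, 1, 1]


@pytest.mark.parametrize("seed", range(20))
def test_structural_laws_on_random_trees(seed):
    n = 3 + seed % 8
    g = seed % (max_galls(n) + 1)
    tree = random_galled_tree(n=n, g=g, seed=seed)
    assert validate(tree).ok
    assert tree.n == n and tree.g == g
    assert len(tree.internal_nodes) == n - 1 + 2 * g
    assert event_count(tree) == n - 1


def test_structural_laws_on_many_random_fixtures():
    # internal nodes = n - 1 + 2g and events = n - 1 across 1,000 draws
    for seed in range(1000):
        n = 2 + seed % 9
        g = seed % (max_galls(n) + 1)
        tree = random_galled_tree(n=n, g=g, seed=seed)
        assert len(tree.internal_nodes) == tree.n - 1 + 2 * tree.g
        assert event_count(tree) == tree.n - 1


def test_generator_rejects_infeasible_gall_count():
    with pytest.raises(InfeasibleError):
        random_galled_tree(n=4, g=2, seed=0)  # needs 2g+1 = 5 leaves


def test_structural_laws_on_enumerated_trees(all_trees_to_6):
    for tree in all_trees_to_6:
        assert validate(tree).ok
        assert len(tree.internal_nodes) == tree.n - 1 + 2 * tree.g
        assert event_count(tree) == tree.n - 1
        assert tree.g <= max_galls(tree.n)


def test_postorder_numbering_reproduces_display_convention(single_gall):
    num = postorder_numbering(single_gall)
    (gall,) = find_galls(single_gall)
    assert num[gall.top] == 12
    assert num[gall.hybrid] == 5
    assert {num[gall.left_hybridizing], num[gall.right_hybridizing]} == {6, 7}
    assert [num[s] for s in gall.left_side] == [8]
    assert sorted(num[s] for s in gall.right_side) == [10, 11]
    # hybrid subtree gets the smallest available number in the gall region
    hybrid_sub_root = off_cycle_child(single_gall, gall, gall.hybrid)
    assert num[hybrid_sub_root] < num[gall.hybrid]
    # children numbered before parents throughout
    for u, v in single_gall.edges:
        if not single_gall.is_leaf(v):
            assert num[v] < num[u]
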