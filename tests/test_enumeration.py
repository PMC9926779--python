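"""Exhaustive enumeration of small galled trees and canonical forms."""

import pytest

from gallhist import (
    canonical_form,
    count_labeled_histories,
    enumerate_galled,
    enumerate_gallfree,
    max_histories_table,
    validate,
    wedderburn_etherington,
)
from gallhist.enumeration import (
    canonical_shape,
    galled_shapes,
    naive_galled_shapes,
    structured_root_gall_shapes,
)
from gallhist.errors import DomainError
from gallhist.model import LEAF, GalledTree, shape_gall_count


WE_EXPECTED = {1: 1, 2: 1, 3: 1, 4: 2, 5: 3, 6: 6, 7: 11, 8: 23}
TOTALS = {1: 1, 2: 1, 3: 2, 4: 6, 5: 20, 6: 72}


@pytest.mark.parametrize("n,expected", sorted(WE_EXPECTED.items()))
def test_wedderburn_etherington_values(n, expected):
    assert wedderburn_etherington(n) == expected


def test_wedderburn_etherington_domain():
    with pytest.raises(DomainError):
        wedderburn_etherington(0)


@pytest.mark.parametrize("n", range(1, 9))
def test_gallfree_enumeration_matches_recursion(n):
    trees = enumerate_gallfree(n)
    assert len(trees) == wedderburn_etherington(n)
    assert all(t.g == 0 and t.n == n for t in trees)


@pytest.mark.parametrize("n,total", sorted(TOTALS.items()))
def test_galled_tree_totals(n, total):
    trees = enumerate_galled(n)
    assert len(trees) == total
    keys = {canonical_form(t) for t in trees}
    assert len(keys) == total  # all distinct canonical forms
    for t in trees:
        assert validate(t).ok


def test_gall_strata():
    by_g = lambda n: {
        g: len(enumerate_galled(n, g))
        for g in range((n - 1) // 2 + 1)
    }
    assert by_g(4) == {0: 2, 1: 4}
    assert by_g(5) == {0: 3, 1: 15, 2: 2}
    assert by_g(6) == {0: 6, 1: 48, 2: 18}


def test_gallfree_stratum_matches_wedderburn_etherington():
    for n in range(1, 9):
        assert len(galled_shapes(n, 0)) == wedderburn_etherington(n)


def test_infeasible_gall_count_rejected():
    with pytest.raises(DomainError):
        enumerate_galled(4, 2)  # 2 galls need 5 leaves


@pytest.mark.parametrize("n", range(1, 7))
def test_structured_scheme_matches_naive_dedup(n):
    """The composition scheme (reflection handled at the composition level)
    must produce exactly the generate-everything-and-canonicalize set."""
    assert set(galled_shapes(n)) == set(naive_galled_shapes(n))


@pytest.mark.parametrize("n", range(3, 7))
def test_structured_scheme_emits_no_duplicates(n):
    emitted = structured_root_gall_shapes(n)
    assert len(emitted) == len(set(emitted))


def test_canonical_form_invariances():
    # mirror image of a tree node
    a = canonical_shape(("T", LEAF, ("T", LEAF, LEAF)))
    b = canonical_shape(("T", ("T", LEAF, LEAF), LEAF))
    assert a == b
    # reflected gall
    cherry = ("T", LEAF, LEAF)
    fwd = canonical_shape(("G", 1, (cherry, LEAF, LEAF, LEAF)))
    ref = canonical_shape(("G", 0, (LEAF, LEAF, LEAF, cherry)))
    assert fwd == ref


def test_canonical_form_distinguishes_all_small_trees(all_trees_to_6):
    keys = {canonical_form(t) for t in all_trees_to_6}
    assert len(keys) == 102


def test_minimum_leaves_per_gall_count():
    # a tree with g galls needs at least 2g+1 leaves
    for n in range(1, 7):
        for g in range((n - 1) // 2 + 1):
            for t in enumerate_galled(n, g):
                assert t.n >= 2 * t.g + 1


def test_max_histories_table_small():
    records = {(r["n"], r["g"]): r for r in max_histories_table(4)}
    assert records[(4, 0)]["num_trees"] == 2
    assert records[(4, 1)]["num_trees"] == 4
    assert records[(4, 0)]["max_histories"] == 2
    assert records[(4, 1)]["max_histories"] == 1
    records3 = {r["g"]: r for r in max_histories_table(3)}
    assert records3[0]["max_histories"] == 1
    assert records3[1]["max_histories"] == 1


def test_maximum_is_attained_in_gallfree_stratum():
    """No galled tree beats the best gall-free topology on history count."""
    for n in (5, 6):
        records = {r["g"]: r["max_histories"] for r in max_histories_table(n)}
        assert records[0] == max(records.values())
        # and maxima do not increase with the gall count
        maxima = [records[g] for g in sorted(records)]
        assert maxima == sorted(maxima, reverse=True)


def test_decoded_summary_maxima():
    # per-gall-count maxima for 5 and 6 leaves, verified exhaustively
    assert {
        r["g"]: r["max_histories"] for r in max_histories_table(5)
    } == {0: 3, 1: 3, 2: 1}
    assert {
        r["g"]: r["max_histories"] for r in max_histories_table(6)
    } == {0: 8, 1: 6, 2: 6}


def test_enumerated_trees_have_unique_labels(all_trees_to_6):
    for t in all_trees_to_6:
        labels = list(t.leaf_labels.values())
        assert len(set(labels)) == len(labels) == t.n


def test_gall_count_recorded_in_shape(all_trees_to_6):
    from gallhist.model import tree_to_shape

    for t in all_trees_to_6:
        assert shape_gall_count(tree_to_shape(t)) == t.g
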