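"""Combinatorial core: validity, bijection, enumeration, counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnabranch import (
    PlaneTree,
    TwoMotzkinPath,
    catalan,
    degree_summary,
    enumerate_paths,
    enumerate_trees,
    motzkin,
    path_to_tree,
    skeleton,
    tree_to_path,
    validate_path,
)
from rnabranch.trees import InvalidPathError

from .conftest import naive_enumerate_paths


# -- validity ---------------------------------------------------------------


@pytest.mark.parametrize(
    "s, ok",
    [("UD", True), ("DU", False), ("UHID", True), ("", True),
     ("UUDD", True), ("UDD", False), ("UUD", False), ("HIHI", True)],
)
def test_validate_path_examples(s, ok):
    assert validate_path(s) is ok


def test_validate_path_names_foreign_character_position():
    with pytest.raises(InvalidPathError, match="position 3"):
        validate_path("UHXD")


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="UHID", max_size=12))
def test_validate_path_matches_naive_scan(s):
    height = 0
    ok = True
    for ch in s:
        height += {"U": 1, "D": -1}.get(ch, 0)
        if height < 0:
            ok = False
            break
    assert validate_path(s) is (ok and height == 0)


def test_path_accessor_is_one_based():
    x = TwoMotzkinPath("UHD")
    assert x.at(1) == "U" and x.at(3) == "D"
    with pytest.raises(IndexError):
        x.at(0)
    with pytest.raises(InvalidPathError):
        TwoMotzkinPath("DU")


# -- bijection --------------------------------------------------------------


@pytest.mark.parametrize(
    "parens, path",
    [
        ("(()())", "UD"),  # root -> v, v -> {l1, l2}
        ("()()()()", "HHH"),  # star: all root edges -> H
        ("(())", "I"),  # chain root -> a -> b
        ("()", ""),  # single edge: the empty path
    ],
)
def test_bijection_hand_examples(parens, path):
    tree = PlaneTree.from_parens(parens)
    assert str(tree_to_path(tree)) == path
    assert path_to_tree(path) == tree


def test_empty_tree_has_no_path():
    with pytest.raises(ValueError):
        tree_to_path(PlaneTree(()))


@pytest.mark.parametrize("n", range(1, 9))
def test_bijection_roundtrip_and_statistic_transport(n):
    """On the full enumeration of trees with n <= 8 edges, the path map is a
    bijection onto length-(n-1) paths and transports d0, d1 onto symbol
    counts: |x|_I = d1 and |x|_U + |x|_H + 1 = d0."""
    trees = enumerate_trees(n)
    assert len(trees) == catalan(n)
    images = set()
    for tree in trees:
        x = tree_to_path(tree)
        assert len(x) == n - 1
        assert path_to_tree(x) == tree
        ds = degree_summary(tree)
        assert x.count("I") == ds.d1
        assert x.count("U") + x.count("H") + 1 == ds.d0
        images.add(str(x))
    assert len(images) == catalan(n)  # injective onto all paths


@pytest.mark.parametrize("m", range(0, 8))
def test_path_roundtrip_from_path_side(m):
    for x in enumerate_paths(m):
        assert tree_to_path(path_to_tree(x)) == x


# -- degree summaries -------------------------------------------------------


@pytest.mark.parametrize(
    "parens, n, d0, d1, r",
    [
        ("()()()()()", 5, 5, 0, 5),  # star with 5 children
        ("((()))", 3, 1, 2, 1),  # chain of length 3
        ("()", 1, 1, 0, 1),  # single edge
    ],
)
def test_degree_summary_examples(parens, n, d0, d1, r):
    ds = degree_summary(PlaneTree.from_parens(parens))
    assert (ds.n, ds.d0, ds.d1, ds.root_degree) == (n, d0, d1, r)
    assert sum(ds.down_degree_counts) == n
    assert sum(j * dj for j, dj in enumerate(ds.down_degree_counts)) == n - r


def test_degree_identities_on_enumeration():
    for n in range(1, 8):
        for tree in enumerate_trees(n):
            ds = degree_summary(tree)
            assert ds.n == n
            assert sum(ds.down_degree_counts) == n
            assert sum(j * dj for j, dj in enumerate(ds.down_degree_counts)) == n - ds.root_degree


# -- skeleton ---------------------------------------------------------------


@pytest.mark.parametrize("x, expected", [("UHIDH", "UD"), ("HHH", ""), ("UUDD", "UUDD")])
def test_skeleton_examples(x, expected):
    assert skeleton(x) == expected


def test_skeleton_is_dyck_and_idempotent():
    for x in enumerate_paths(6):
        sk = skeleton(x)
        assert set(sk) <= {"U", "D"}
        assert validate_path(sk)
        assert skeleton(sk) == sk


# -- enumeration and counting ----------------------------------------------


@pytest.mark.parametrize("m", range(0, 7))
def test_enumerate_paths_matches_naive_filter(m):
    assert [str(x) for x in enumerate_paths(m)] == naive_enumerate_paths(m)


def test_enumerate_paths_counts_and_examples():
    assert [str(x) for x in enumerate_paths(0)] == [""]
    assert sorted(str(x) for x in enumerate_paths(1)) == ["H", "I"]
    assert sorted(str(x) for x in enumerate_paths(2)) == ["HH", "HI", "IH", "II", "UD"]
    for m in range(0, 9):
        assert len(enumerate_paths(m)) == catalan(m + 1)


def test_enumeration_cap_enforced():
    with pytest.raises(ValueError, match="cap"):
        enumerate_paths(11)
    with pytest.raises(ValueError):
        enumerate_paths(-1)


def test_catalan_and_motzkin_values():
    assert [catalan(n) for n in range(9)] == [1, 1, 2, 5, 14, 42, 132, 429, 1430]
    assert motzkin(3) == 4
    # formula vs brute force: Motzkin paths are the I-free 2-Motzkin paths
    for n in range(0, 9):
        assert motzkin(n) == sum(1 for x in enumerate_paths(n) if "I" not in str(x))
    with pytest.raises(ValueError):
        catalan(-1)
    with pytest.raises(ValueError):
        motzkin(-2)


# -- serialization ----------------------------------------------------------


def test_parens_round_trip_on_enumeration():
    for n in range(1, 7):
        for tree in enumerate_trees(n):
            text = tree.to_parens()
            assert len(text) == 2 * n
            assert PlaneTree.from_parens(text) == tree


def test_parens_parse_errors():
    with pytest.raises(ValueError):
        PlaneTree.from_parens("(()")
    with pytest.raises(ValueError):
        PlaneTree.from_parens("())(")
    with pytest.raises(ValueError, match="position"):
        PlaneTree.from_parens("(x)")


def test_newick_export_shape():
    assert PlaneTree.from_parens("(()())").to_newick() == "((,));"
    assert PlaneTree.from_parens("()").to_newick() == "();"
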