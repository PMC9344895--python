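"""Plane trees, 2-Motzkin paths, and the bijection between them.

A plane tree (rooted, ordered tree) models the branching pattern of an RNA
secondary structure: the root is the exterior loop, each edge a helix, each
leaf a hairpin, each non-root degree-1 node an interior loop, and each
non-root node of down degree >= 2 a multiloop.

A 2-Motzkin path is a lattice path over the step alphabet ``U`` (up), ``D``
(down), and two colours of horizontal step ``H`` and ``I``, that never dips
below the axis and ends on it.  Plane trees with ``n`` edges are in bijection
(due to Deutsch) with 2-Motzkin paths of length ``n - 1``; the bijection
transports the leaf count d0 and the interior-node count d1 onto simple
symbol counts of the path, which is what makes the path the natural state
space for sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

__all__ = [
    "PlaneTree",
    "TwoMotzkinPath",
    "validate_path",
    "tree_to_path",
    "path_to_tree",
    "degree_summary",
    "skeleton",
    "enumerate_paths",
    "enumerate_trees",
    "catalan",
    "motzkin",
]

PATH_ALPHABET = frozenset("UHID")

#: default cap on enumeration length (4**10 candidate strings at the cap)
ENUMERATION_CAP = 10


class InvalidPathError(ValueError):
    """Raised when a string is not a valid 2-Motzkin path."""


def _check_alphabet(symbols: str) -> None:
    for pos, ch in enumerate(symbols, start=1):
        if ch not in PATH_ALPHABET:
            raise InvalidPathError(
                f"symbol {ch!r} at position {pos} is not one of U, H, I, D"
            )


def validate_path(symbols: str) -> bool:
    """Return True iff ``symbols`` is a valid 2-Motzkin path.

    Valid means: drawn from {U, H, I, D}, the number of D steps never
    exceeds the number of U steps in any prefix, and the totals are equal
    (the path returns to the axis).  A foreign character raises
    :class:`InvalidPathError` naming its position.
    """
    _check_alphabet(symbols)
    height = 0
    for ch in symbols:
        if ch == "U":
            height += 1
        elif ch == "D":
            height -= 1
            if height < 0:
                return False
    return height == 0


@dataclass(frozen=True)
class TwoMotzkinPath:
    """A validated 2-Motzkin path; the Markov chain's state.

    ``symbols`` is the string form.  Positions are 1-based in the public
    API, matching the lattice-path convention used throughout.
    """

    symbols: str

    def __post_init__(self) -> None:
        if not validate_path(self.symbols):
            raise InvalidPathError(f"{self.symbols!r} is not a valid 2-Motzkin path")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def m(self) -> int:
        return len(self.symbols)

    def at(self, k: int) -> str:
        """Symbol at 1-based position ``k``."""
        if not 1 <= k <= len(self.symbols):
            raise IndexError(f"position {k} outside 1..{len(self.symbols)}")
        return self.symbols[k - 1]

    def count(self, symbol: str) -> int:
        return self.symbols.count(symbol)

    @property
    def counts(self) -> dict[str, int]:
        return {a: self.symbols.count(a) for a in "UHID"}

    def __str__(self) -> str:
        return self.symbols


# ---------------------------------------------------------------------------
# Plane trees
# ---------------------------------------------------------------------------

Node = tuple  # a node is the tuple of its child subtrees


@dataclass(frozen=True)
class PlaneTree:
    """Rooted ordered tree, stored as nested tuples of children.

    The root is ``self.root``; each node is the tuple of its ordered child
    subtrees, so a leaf is ``()``.  Structural equality is tree equality.
    """

    root: Node

    @property
    def n_edges(self) -> int:
        def count(node: Node) -> int:
            return len(node) + sum(count(c) for c in node)

        return count(self.root)

    @property
    def root_degree(self) -> int:
        return len(self.root)

    # -- serialization ------------------------------------------------------

    def to_parens(self) -> str:
        """Balanced-parenthesis form: each child subtree rendered as
        ``( ... )``, concatenated left-to-right inside its parent."""

        def render(node: Node) -> str:
            return "".join("(" + render(c) + ")" for c in node)

        return render(self.root)

    @classmethod
    def from_parens(cls, text: str) -> "PlaneTree":
        text = text.strip()
        stack: list[list] = [[]]
        for pos, ch in enumerate(text, start=1):
            if ch == "(":
                stack.append([])
            elif ch == ")":
                if len(stack) == 1:
                    raise ValueError(f"unbalanced ')' at position {pos}")
                done = stack.pop()
                stack[-1].append(tuple(done))
            else:
                raise ValueError(f"unexpected character {ch!r} at position {pos}")
        if len(stack) != 1:
            raise ValueError("unbalanced '(' in tree string")

        def freeze(children: list) -> Node:
            return tuple(children)

        return cls(freeze(stack[0]))

    def to_newick(self) -> str:
        """Newick form with labels omitted, for tree viewers."""

        def render(node: Node) -> str:
            if not node:
                return ""
            return "(" + ",".join(render(c) for c in node) + ")"

        return render(self.root) + ";"

    def __str__(self) -> str:
        return self.to_parens()


@dataclass(frozen=True)
class DegreeSummary:
    n: int
    d0: int  # leaves (hairpins)
    d1: int  # non-root nodes with exactly one child (interior loops)
    root_degree: int
    down_degree_counts: tuple  # d_j for j = 0..max over non-root nodes
    max_down_degree: int  # over non-root nodes


def degree_summary(tree: PlaneTree) -> DegreeSummary:
    """Degree statistics of a plane tree in a single traversal.

    Down-degree counts d_j tally non-root nodes only; the root (exterior
    loop) is reported separately through ``root_degree``.  The identities
    sum(d_j) = n and sum(j * d_j) = n - r always hold.
    """
    counts: dict[int, int] = {}

    stack = list(tree.root)  # children of root; root itself excluded from d_j
    n = len(tree.root)
    while stack:
        node = stack.pop()
        deg = len(node)
        counts[deg] = counts.get(deg, 0) + 1
        n += deg
        stack.extend(node)

    max_deg = max(counts) if counts else 0
    d_j = tuple(counts.get(j, 0) for j in range(max_deg + 1))
    return DegreeSummary(
        n=n,
        d0=counts.get(0, 0),
        d1=counts.get(1, 0),
        root_degree=len(tree.root),
        down_degree_counts=d_j,
        max_down_degree=max_deg,
    )


# ---------------------------------------------------------------------------
# The Deutsch bijection
# ---------------------------------------------------------------------------


def tree_to_path(tree: PlaneTree) -> TwoMotzkinPath:
    """Map a plane tree with n >= 1 edges to its 2-Motzkin path of length n-1.

    Each edge is labelled by where it sits below its parent: off the root
    (or strictly interior among >= 3 siblings) -> H; the only edge off a
    degree-1 non-root node -> I; leftmost / rightmost of >= 2 siblings off a
    non-root node -> U / D.  Reading labels in preorder always starts with
    H; that initial H is dropped.
    """
    if not tree.root:
        raise ValueError("the empty tree (n=0) has no corresponding path")

    labels: list[str] = []

    def visit(node: Node, is_root: bool) -> None:
        k = len(node)
        for idx, child in enumerate(node):
            if is_root:
                label = "H"
            elif k == 1:
                label = "I"
            elif idx == 0:
                label = "U"
            elif idx == k - 1:
                label = "D"
            else:
                label = "H"
            labels.append(label)
            visit(child, False)

    visit(tree.root, True)
    assert labels[0] == "H"
    return TwoMotzkinPath("".join(labels[1:]))


def path_to_tree(path: TwoMotzkinPath | str) -> PlaneTree:
    """Inverse bijection: build the plane tree with m+1 edges from a path.

    Stack-based reconstruction: ``u`` is the node that receives new children
    for H and D symbols, ``v`` is always the last node added, and the stack
    holds suspended values of ``u``.  The root edge consumed by the dropped
    initial H of the forward map is pre-seeded.
    """
    if isinstance(path, str):
        path = TwoMotzkinPath(path)

    class _N:
        __slots__ = ("children",)

        def __init__(self) -> None:
            self.children: list["_N"] = []

    root = _N()
    u = root
    v = _N()
    stack: list[_N] = []
    root.children.append(v)
    for ch in path.symbols:
        node = _N()
        if ch == "U":
            v.children.append(node)
            stack.append(u)
            u = v
        elif ch == "I":
            v.children.append(node)
        elif ch == "H":
            u.children.append(node)
        elif ch == "D":
            u.children.append(node)
            u = stack.pop()
        v = node

    def freeze(node: _N) -> Node:
        return tuple(freeze(c) for c in node.children)

    return PlaneTree(freeze(root))


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------


def skeleton(path: TwoMotzkinPath | str) -> str:
    """The Dyck-path skeleton: the U/D subsequence of the path."""
    symbols = path.symbols if isinstance(path, TwoMotzkinPath) else path
    if isinstance(path, str) and not validate_path(path):
        raise InvalidPathError(f"{path!r} is not a valid 2-Motzkin path")
    return "".join(ch for ch in symbols if ch in "UD")


# ---------------------------------------------------------------------------
# Enumeration and counting
# ---------------------------------------------------------------------------


def enumerate_paths(m: int, cap: int = ENUMERATION_CAP) -> list[TwoMotzkinPath]:
    """All valid 2-Motzkin paths of length ``m``, lexicographic in D<H<I<U.

    Generated by depth-first extension with prefix pruning (a prefix is
    extendable iff its height can still return to 0 within the remaining
    steps).  The count is catalan(m+1).
    """
    if m < 0:
        raise ValueError("length must be nonnegative")
    if m > cap:
        raise ValueError(
            f"enumeration length {m} exceeds the cap {cap}; "
            f"raise the cap explicitly if you really want 4^{m} candidates"
        )

    out: list[TwoMotzkinPath] = []
    buf: list[str] = []

    def extend(height: int, remaining: int) -> None:
        if remaining == 0:
            if height == 0:
                out.append(TwoMotzkinPath("".join(buf)))
            return
        for ch, dh in (("D", -1), ("H", 0), ("I", 0), ("U", 1)):
            h2 = height + dh
            if h2 < 0 or h2 > remaining - 1:
                continue
            buf.append(ch)
            extend(h2, remaining - 1)
            buf.pop()

    extend(0, m)
    return out


@lru_cache(maxsize=None)
def _forests(n: int) -> tuple:
    # ordered forests (tuples of subtrees) with n edges total
    if n == 0:
        return ((),)
    out = []
    for k in range(1, n + 1):  # edges used by the first subtree incl. its stem
        for first_children in _forests(k - 1):
            for rest in _forests(n - k):
                out.append((first_children,) + rest)
    return tuple(out)


def enumerate_trees(n: int, cap: int = ENUMERATION_CAP + 1) -> list[PlaneTree]:
    """All plane trees with ``n`` edges, by recursive subtree composition.

    Independent of the path bijection; the count is catalan(n).
    """
    if n < 0:
        raise ValueError("edge count must be nonnegative")
    if n > cap:
        raise ValueError(f"edge count {n} exceeds the cap {cap}")
    return [PlaneTree(children) for children in _forests(n)]


def catalan(n: int) -> int:
    """The n-th Catalan number C_n = binom(2n, n) / (n + 1), exact."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return math.comb(2 * n, n) // (n + 1)


def motzkin(n: int) -> int:
    """The n-th Motzkin number, by the sum over binom(n, 2k) * C_k."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return sum(math.comb(n, 2 * k) * catalan(k) for k in range(n // 2 + 1))
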