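"""Enumeration of candidate substrings, subtrees, and divisions.

Each candidate becomes a binary variable of the integer program:

* substrings ``s[i..j]`` of the input string (``x`` variables),
* subtree indices ``T[i, t, h, k]`` / ``T[i, t, C]`` (``x`` variables),
* divisions of a subtree into two parts (``y`` variables):

  - *horizontal*: split the child span (ordered) or child set (unordered) of
    the subtree's root into two nonempty parts; the tag, if any, stays on the
    unique side whose children contain it;
  - *vertical*: pick an internal vertex ``t`` of the subtree; the upper part
    is the subtree tagged at ``t``, the lower part is ``t`` with all of its
    children.  For an already-tagged subtree (tag ``j``), ``t`` must be a
    strict ancestor of ``j`` -- otherwise a part would carry two tags.

Subtree candidates are generated top-down from the whole tree, so only
indices reachable in some derivation become variables.  Base elements of the
recursion are single untagged leaf edges ``T[i, eps, c, c]`` and single tagged
edges ``T[i, c, c, c]`` with ``c`` internal (a tag at a leaf admits no
attachment and is never generated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .tree import (
    EPSILON,
    LabeledTree,
    OrderedSubtree,
    Subtree,
    TreeError,
    UnorderedSubtree,
)


class DegreeGuardError(TreeError):
    """Unordered enumeration refused: some vertex has too many children."""


@dataclass(frozen=True)
class Division:
    """One legal bisection of ``parent`` into ``left`` and ``right``.

    ``kind`` is ``"H"`` (horizontal, at the root) or ``"V"`` (vertical, at an
    internal vertex that becomes a tag).  ``where`` identifies the split:
    the last child on the left side (ordered horizontal), the split vertex
    (vertical), or the sorted left child subset (unordered horizontal).
    Unordered horizontal splits are generated once per unordered subset pair.
    """

    parent: Subtree
    kind: str
    where: object
    left: Subtree
    right: Subtree


@dataclass
class Enumeration:
    """All candidate subtrees and divisions of one tree, in discovery order."""

    root: Subtree
    subtrees: list
    divisions: list
    by_parent: dict
    base: list

    @property
    def n_horizontal(self) -> int:
        return sum(1 for d in self.divisions if d.kind == "H")

    @property
    def n_vertical(self) -> int:
        return sum(1 for d in self.divisions if d.kind == "V")


def enumerate_substrings(s: str) -> list[tuple[int, int]]:
    """All 1-based closed spans ``(i, j)`` with ``1 <= i <= j <= n``."""
    n = len(s)
    if n == 0:
        raise ValueError("empty string")
    return [(i, j) for i in range(1, n + 1) for j in range(i, n + 1)]


# -- ordered trees ---------------------------------------------------------

def ordered_divisions(tree: LabeledTree, sub: OrderedSubtree) -> list[Division]:
    """All legal divisions of one ordered subtree index."""
    tree.validate_ordered(sub)
    if tree.is_base_ordered(sub):
        return []
    i, j = sub.root, sub.tag
    span = tree.span_children(sub)
    divs: list[Division] = []
    # horizontal: split the child span after position l
    tag_top = None if j is EPSILON else tree.top_child_of(i, j)
    for pos in range(len(span) - 1):
        l, nxt = span[pos], span[pos + 1]
        left_set = set(span[: pos + 1])
        jl, jr = (EPSILON, EPSILON)
        if j is not EPSILON:
            if tag_top in left_set:
                jl = j
            else:
                jr = j
        left = OrderedSubtree(i, jl, sub.h, l)
        right = OrderedSubtree(i, jr, nxt, sub.k)
        divs.append(Division(sub, "H", l, left, right))
    # vertical: tag an internal vertex t
    if j is EPSILON:
        candidates = tree.internal_vertices(sub)
    else:
        inside = tree.subtree_vertices(sub)
        candidates = sorted(t for t in tree.an(j) if t in inside and t != i)
    for t in candidates:
        upper = OrderedSubtree(i, t, sub.h, sub.k)
        lower = OrderedSubtree(t, j, tree.lch(t), tree.rch(t))
        divs.append(Division(sub, "V", t, upper, lower))
    return divs


def enumerate_ordered(tree: LabeledTree) -> Enumeration:
    """Reachable ordered subtree indices and their divisions, top-down from
    the whole tree ``T[1, eps, lch(1), rch(1)]``."""
    root = tree.whole_ordered()
    return _close(tree, root, ordered_divisions, tree.is_base_ordered)


# -- unordered trees -------------------------------------------------------

def unordered_divisions(tree: LabeledTree, sub: UnorderedSubtree) -> list[Division]:
    """All legal divisions of one unordered subtree index.

    Horizontal splits are unordered pairs of nonempty subsets ``{C1, C2}``;
    each pair is generated once (the side holding the smallest child is the
    left part).
    """
    tree.validate_unordered(sub)
    if tree.is_base_unordered(sub):
        return []
    i, j = sub.root, sub.tag
    C = sorted(sub.children)
    divs: list[Division] = []
    tag_top = None if j is EPSILON else tree.top_child_of(i, j)
    anchor, others = C[0], C[1:]
    # every subset C1 containing the anchor, C1 != C
    for mask in range(2 ** len(others) - 1):
        c1 = {anchor}
        for b, c in enumerate(others):
            if mask >> b & 1:
                c1.add(c)
        c2 = set(C) - c1
        jl, jr = (EPSILON, EPSILON)
        if j is not EPSILON:
            if tag_top in c1:
                jl = j
            else:
                jr = j
        left = UnorderedSubtree(i, jl, frozenset(c1))
        right = UnorderedSubtree(i, jr, frozenset(c2))
        divs.append(Division(sub, "H", tuple(sorted(c1)), left, right))
    if j is EPSILON:
        candidates = tree.internal_vertices(sub)
    else:
        inside = tree.subtree_vertices(sub)
        candidates = sorted(t for t in tree.an(j) if t in inside and t != i)
    for t in candidates:
        upper = UnorderedSubtree(i, t, sub.children)
        lower = UnorderedSubtree(t, j, frozenset(tree.ch(t)))
        divs.append(Division(sub, "V", t, upper, lower))
    return divs


def enumerate_unordered(tree: LabeledTree, max_children: int = 16) -> Enumeration:
    """Reachable unordered subtree indices and divisions.

    The number of child-subset candidates grows exponentially in vertex
    degree, so enumeration refuses trees where some vertex has more than
    ``max_children`` children (exact unordered solving is impractical at high
    degree).
    """
    for v in tree.vertices():
        if len(tree.ch(v)) > max_children:
            raise DegreeGuardError(
                f"vertex {v} has {len(tree.ch(v))} children "
                f"(> max_children={max_children}); unordered enumeration refused"
            )
    root = tree.whole_unordered()
    return _close(tree, root, unordered_divisions, tree.is_base_unordered)


# -- shared closure --------------------------------------------------------

def _close(tree, root, divide, is_base) -> Enumeration:
    subtrees: list = []
    seen: set = set()
    divisions: list[Division] = []
    by_parent: dict = {}
    base: list = []
    queue = [root]
    seen.add(root)
    while queue:
        sub = queue.pop()
        subtrees.append(sub)
        if is_base(sub):
            base.append(sub)
            by_parent[sub] = []
            continue
        divs = divide(tree, sub)
        by_parent[sub] = divs
        divisions.extend(divs)
        for d in divs:
            for part in (d.left, d.right):
                if part not in seen:
                    seen.add(part)
                    queue.append(part)
    return Enumeration(root, subtrees, divisions, by_parent, base)
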