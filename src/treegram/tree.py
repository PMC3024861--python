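"""Rooted edge-labeled trees, tagged subtrees, and Euler-string canonicalization.

The central objects are:

* :class:`LabeledTree` -- a rooted tree whose edges carry labels from a finite
  terminal alphabet.  Vertices are numbered ``1..n`` in preorder with the root
  at ``1``; every child list is ordered left-to-right.  In *unordered* mode the
  same object is used but child order carries no meaning.

* :class:`OrderedSubtree` ``T[i, t, h, k]`` -- the subtree rooted at vertex
  ``i`` spanning children ``h..k`` of ``i`` together with their full descendant
  subtrees, truncated below the *tag* vertex ``t`` (``t`` is :data:`EPSILON`
  for an untagged subtree).  A tag marks the vertex where another tree may be
  attached at its root; a tree contains at most one tag.

* :class:`UnorderedSubtree` ``T[i, t, C]`` -- the unordered analogue, where
  ``C`` is a nonempty subset of the children of ``i``.

* :class:`EulerString` -- the depth-first serialization of a (possibly
  tagged) subtree with matched open/close symbols per edge label and a single
  tag marker emitted between the open and close symbols of the tagged edge.
  Two ordered subtrees are isomorphic iff their Euler strings are equal; for
  unordered subtrees the same holds after canonicalization
  (:func:`canonicalize_unordered`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence, Union


class TreeError(ValueError):
    """Raised for malformed trees or invalid subtree indices."""


class _Epsilon:
    """Singleton sentinel for 'no tag'.  Not a vertex id."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ε"

    def __reduce__(self):
        return (_Epsilon, ())


#: The 'untagged' sentinel.  Never exposed as a vertex id.
EPSILON = _Epsilon()

Tag = Union[int, _Epsilon]

# Euler-string tokens.  Closing symbols are distinct tokens per label (never a
# string decoration) so arbitrary label alphabets are safe.
TAG_TOKEN = ("x",)


def open_token(label: str) -> tuple:
    return ("o", label)


def close_token(label: str) -> tuple:
    return ("c", label)


def _validate_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise TreeError(f"edge label must be a non-empty string, got {label!r}")
    if any(c.isspace() for c in label) or label == "*" or label.startswith("/"):
        raise TreeError(
            f"edge label {label!r} may not contain whitespace, equal '*', "
            "or start with '/' (reserved by the text rendering)"
        )
    return label


@dataclass(frozen=True)
class EulerString:
    """Canonical string identifier of a (possibly tagged) subtree.

    ``tokens`` is a tuple of ``("o", label)`` / ``("c", label)`` pairs plus at
    most one tag marker ``("x",)``.  Equality of Euler strings is equality of
    token tuples.
    """

    tokens: tuple

    def __post_init__(self):
        depth = 0
        tags = 0
        stack: list[str] = []
        for tok in self.tokens:
            if tok == TAG_TOKEN:
                tags += 1
            elif tok[0] == "o":
                stack.append(tok[1])
                depth += 1
            elif tok[0] == "c":
                if not stack or stack[-1] != tok[1]:
                    raise TreeError(f"unbalanced Euler string: {self.tokens!r}")
                stack.pop()
            else:  # pragma: no cover - defensive
                raise TreeError(f"unknown token {tok!r}")
        if stack:
            raise TreeError(f"unbalanced Euler string: {self.tokens!r}")
        if tags > 1:
            raise TreeError("an Euler string contains at most one tag marker")

    @property
    def text(self) -> str:
        """Space-separated rendering: open = label, close = /label, tag = *."""
        out = []
        for tok in self.tokens:
            if tok == TAG_TOKEN:
                out.append("*")
            elif tok[0] == "o":
                out.append(tok[1])
            else:
                out.append("/" + tok[1])
        return " ".join(out)

    @classmethod
    def from_text(cls, text: str) -> "EulerString":
        toks = []
        for piece in text.split():
            if piece == "*":
                toks.append(TAG_TOKEN)
            elif piece.startswith("/"):
                toks.append(close_token(piece[1:]))
            else:
                toks.append(open_token(piece))
        return cls(tuple(toks))

    @property
    def n_edges(self) -> int:
        return sum(1 for t in self.tokens if t[0] == "o" and t != TAG_TOKEN)

    @property
    def n_vertices(self) -> int:
        return self.n_edges + 1

    @property
    def has_tag(self) -> bool:
        return TAG_TOKEN in self.tokens

    def labels(self) -> list[str]:
        """Multiset (sorted list) of edge labels."""
        return sorted(t[1] for t in self.tokens if t[0] == "o" and t != TAG_TOKEN)

    def __str__(self) -> str:
        return self.text


class OrderedSubtree(NamedTuple):
    """Index ``T[i, t, h, k]``: root ``i``, tag ``t`` (or EPSILON), leftmost
    child ``h`` and rightmost child ``k`` of ``i``."""

    root: int
    tag: Tag
    h: int
    k: int

    def __repr__(self) -> str:
        return f"T[{self.root},{self.tag},{self.h},{self.k}]"


class UnorderedSubtree(NamedTuple):
    """Index ``T[i, t, C]``: root ``i``, tag ``t`` (or EPSILON), child subset
    ``C`` (a frozenset, nonempty)."""

    root: int
    tag: Tag
    children: frozenset

    def __repr__(self) -> str:
        cs = ",".join(str(c) for c in sorted(self.children))
        return f"T[{self.root},{self.tag},{{{cs}}}]"


Subtree = Union[OrderedSubtree, UnorderedSubtree]


class LabeledTree:
    """Rooted tree with labeled edges and explicit child order.

    Vertices are ``1..n`` in preorder (root = 1).  Each non-root vertex ``v``
    carries the label of its parent edge, accessible as ``label(v)``.
    Construct with :meth:`from_edges`; arbitrary input ids are renumbered to
    preorder and preserved in :attr:`original_ids`.
    """

    def __init__(
        self,
        children: dict[int, tuple[int, ...]],
        labels: dict[int, str],
        original_ids: dict[int, object] | None = None,
    ):
        self._children = children
        self._labels = labels
        self._parent: dict[int, int] = {}
        for p, cs in children.items():
            for c in cs:
                self._parent[c] = p
        self.original_ids = original_ids or {}
        self._check()

    def _check(self) -> None:
        n = 1 + len(self._parent)
        verts = set(range(1, n + 1))
        if set(self._labels) != verts - {1}:
            raise TreeError("every non-root vertex needs exactly one parent edge label")
        for v in verts - {1}:
            if v not in self._parent:
                raise TreeError(f"vertex {v} has no parent (forest or gap in numbering)")
        for p, cs in self._children.items():
            if list(cs) != sorted(cs):
                raise TreeError(
                    f"children of {p} are not in preorder: {cs} (preorder "
                    "numbering requires ascending child ids)"
                )
        # preorder: every child id exceeds its parent's; DFS left-to-right is 1..n
        order = list(self.preorder())
        if order != list(range(1, n + 1)):
            raise TreeError(f"vertex numbering is not preorder: DFS gives {order}")
        for v in self._labels.values():
            _validate_label(v)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[object, object, str]]
    ) -> "LabeledTree":
        """Build from ``(parent, child, label)`` records.

        Sibling order is the order of appearance of each parent's child
        records.  Vertices are renumbered to 1-based preorder; the original
        ids are kept in :attr:`original_ids` (new id -> original id).
        """
        if not edges:
            raise TreeError("a tree needs at least one edge")
        kids: dict[object, list[object]] = {}
        label_of: dict[object, str] = {}
        seen_child: set[object] = set()
        for p, c, lab in edges:
            if c in seen_child:
                raise TreeError(f"vertex {c!r} has two parents")
            seen_child.add(c)
            kids.setdefault(p, []).append(c)
            label_of[c] = _validate_label(lab)
        roots = [p for p in kids if p not in seen_child]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}: {roots!r}")
        root = roots[0]
        # preorder renumbering (iterative DFS, left-to-right)
        new_id: dict[object, int] = {}
        stack = [root]
        while stack:
            v = stack.pop()
            if v in new_id:
                raise TreeError(f"cycle through vertex {v!r}")
            new_id[v] = len(new_id) + 1
            stack.extend(reversed(kids.get(v, [])))
        if len(new_id) != len(seen_child) + 1:
            raise TreeError("input edges do not form a single connected tree")
        children = {
            new_id[p]: tuple(new_id[c] for c in cs) for p, cs in kids.items()
        }
        labels = {new_id[c]: lab for c, lab in label_of.items()}
        original = {v: o for o, v in new_id.items()}
        return cls(children, labels, original)

    # -- basic accessors ---------------------------------------------------
    @property
    def root(self) -> int:
        return 1

    @property
    def n_vertices(self) -> int:
        return 1 + len(self._labels)

    @property
    def n_edges(self) -> int:
        return len(self._labels)

    def vertices(self) -> range:
        return range(1, self.n_vertices + 1)

    def preorder(self) -> Iterator[int]:
        stack = [1]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.ch(v)))

    def ch(self, v: int) -> tuple[int, ...]:
        """Ordered child tuple of ``v`` (empty for leaves)."""
        return self._children.get(v, ())

    def lch(self, v: int) -> int:
        cs = self.ch(v)
        if not cs:
            raise TreeError(f"vertex {v} has no children")
        return cs[0]

    def rch(self, v: int) -> int:
        cs = self.ch(v)
        if not cs:
            raise TreeError(f"vertex {v} has no children")
        return cs[-1]

    def parent(self, v: int) -> int:
        if v == 1:
            raise TreeError("the root has no parent")
        return self._parent[v]

    def an(self, v: int) -> set[int]:
        """Strict ancestors of ``v`` (``v`` itself excluded)."""
        out = set()
        while v != 1:
            v = self._parent[v]
            out.add(v)
        return out

    def label(self, v: int) -> str:
        """Label of the edge from ``parent(v)`` to ``v``."""
        return self._labels[v]

    def is_leaf(self, v: int) -> bool:
        return not self.ch(v)

    def is_internal(self, v: int) -> bool:
        """Neither the root nor a leaf."""
        return v != 1 and bool(self.ch(v))

    def max_children(self) -> int:
        return max((len(cs) for cs in self._children.values()), default=0)

    def degree(self, v: int) -> int:
        return len(self.ch(v)) + (0 if v == 1 else 1)

    def edges(self) -> Iterator[tuple[int, int, str]]:
        for p in sorted(self._children):
            for c in self._children[p]:
                yield (p, c, self._labels[c])

    def label_multiset(self) -> list[str]:
        return sorted(self._labels.values())

    # -- subtree indices ---------------------------------------------------
    def whole_ordered(self) -> OrderedSubtree:
        return OrderedSubtree(1, EPSILON, self.lch(1), self.rch(1))

    def whole_unordered(self) -> UnorderedSubtree:
        return UnorderedSubtree(1, EPSILON, frozenset(self.ch(1)))

    def top_child_of(self, i: int, v: int) -> int:
        """The child of ``i`` on the path from ``i`` down to ``v``."""
        while v in self._parent and self._parent[v] != i:
            v = self._parent[v]
        if self._parent.get(v) != i:
            raise TreeError(f"vertex is not below {i}")
        return v

    def span_children(self, sub: OrderedSubtree) -> tuple[int, ...]:
        cs = self.ch(sub.root)
        hi, ki = cs.index(sub.h), cs.index(sub.k)
        return cs[hi : ki + 1]

    def validate_ordered(self, sub: OrderedSubtree) -> None:
        cs = self.ch(sub.root)
        if sub.h not in cs or sub.k not in cs:
            raise TreeError(f"{sub!r}: h and k must be children of the root")
        if cs.index(sub.h) > cs.index(sub.k):
            raise TreeError(f"{sub!r}: h must not lie right of k")
        if sub.tag is not EPSILON:
            t = sub.tag
            if t == sub.root:
                raise TreeError(f"{sub!r}: the root cannot be the tag")
            span = set(self.span_children(sub))
            if not (t in span or (self.an(t) & span)):
                raise TreeError(f"{sub!r}: tag {t} lies outside the child span")

    def validate_unordered(self, sub: UnorderedSubtree) -> None:
        cs = set(self.ch(sub.root))
        if not sub.children:
            raise TreeError(f"{sub!r}: child subset must be nonempty")
        if not sub.children <= cs:
            raise TreeError(f"{sub!r}: C must be a subset of the root's children")
        if sub.tag is not EPSILON:
            t = sub.tag
            if t == sub.root:
                raise TreeError(f"{sub!r}: the root cannot be the tag")
            if not (t in sub.children or (self.an(t) & sub.children)):
                raise TreeError(f"{sub!r}: tag {t} lies under no child in C")

    def _top_children(self, sub: Subtree) -> tuple[int, ...]:
        if isinstance(sub, OrderedSubtree):
            self.validate_ordered(sub)
            return self.span_children(sub)
        self.validate_unordered(sub)
        return tuple(sorted(sub.children))

    def subtree_vertices(self, sub: Subtree) -> set[int]:
        """All vertices of the (truncated) subtree, including root and tag."""
        tag = sub.tag
        out = {sub.root}
        stack = list(self._top_children(sub))
        while stack:
            v = stack.pop()
            out.add(v)
            if v != tag:
                stack.extend(self.ch(v))
        return out

    def subtree_edges(self, sub: Subtree) -> int:
        """Edge count of the (truncated) subtree."""
        return len(self.subtree_vertices(sub)) - 1

    def internal_vertices(self, sub: Subtree) -> list[int]:
        """Vertices of the subtree that are neither its root nor its leaves.

        The tag vertex is a leaf of the truncated subtree and is excluded.
        """
        tag = sub.tag
        out = []
        stack = list(self._top_children(sub))
        while stack:
            v = stack.pop()
            if v != tag and self.ch(v):
                out.append(v)
                stack.extend(self.ch(v))
        return sorted(out)

    def is_base_ordered(self, sub: OrderedSubtree) -> bool:
        """True iff the index denotes a single (possibly tagged) edge."""
        return sub.h == sub.k and (sub.tag == sub.h or self.is_leaf(sub.h))

    def is_base_unordered(self, sub: UnorderedSubtree) -> bool:
        if len(sub.children) != 1:
            return False
        (c,) = sub.children
        return sub.tag == c or self.is_leaf(c)


# -- Euler strings ---------------------------------------------------------

def euler_string(tree: LabeledTree, sub: OrderedSubtree) -> EulerString:
    """Euler string of the ordered subtree ``T[i, t, h, k]``.

    Depth-first, left-to-right; the edge into vertex ``v`` emits its label on
    descent and the matched closing symbol on ascent.  The tagged edge with
    label ``A`` emits ``A x Ā`` (tag marker between open and close).
    """
    tree.validate_ordered(sub)
    toks: list[tuple] = []

    def emit(v: int) -> None:
        toks.append(open_token(tree.label(v)))
        if v == sub.tag:
            toks.append(TAG_TOKEN)
        else:
            for c in tree.ch(v):
                emit(c)
        toks.append(close_token(tree.label(v)))

    for c in tree.span_children(sub):
        emit(c)
    return EulerString(tuple(toks))


def canonicalize_unordered(tree: LabeledTree, sub: UnorderedSubtree) -> EulerString:
    """Canonical Euler string of an unordered subtree ``T[i, t, C]``.

    Children of every vertex are serialized in sorted order of their own
    canonical edge fragments (label first, then recursively canonicalized
    structure), except that a tag-carrying child is always placed first.  Two
    unordered subtrees receive equal output iff they are unordered-isomorphic;
    the operation is idempotent.
    """
    tree.validate_unordered(sub)

    def frag(v: int) -> tuple:
        lab = tree.label(v)
        if v == sub.tag:
            return (open_token(lab), TAG_TOKEN, close_token(lab))
        inner = _sorted_frags([frag(c) for c in tree.ch(v)])
        return (open_token(lab),) + inner + (close_token(lab),)

    toks = _sorted_frags([frag(c) for c in sorted(sub.children)])
    return EulerString(toks)


def _sorted_frags(frags: list[tuple]) -> tuple:
    tagged = [f for f in frags if TAG_TOKEN in f]
    rest = sorted(f for f in frags if TAG_TOKEN not in f)
    out: list[tuple] = []
    for f in tagged + rest:
        out.extend(f)
    return tuple(out)


def tree_from_euler(es: EulerString) -> tuple[LabeledTree, Tag]:
    """Parse an Euler string back into a tree.

    The serialized forest of edge fragments is hung under a fresh root, which
    mirrors how subtree Euler strings are produced (the subtree root itself
    emits no symbol).  Returns the tree and its tag vertex (or EPSILON).
    """
    edges: list[tuple[int, int, str]] = []
    next_id = 1
    stack = [1]
    tag: Tag = EPSILON
    for tok in es.tokens:
        if tok == TAG_TOKEN:
            tag = stack[-1]
        elif tok[0] == "o":
            next_id += 1
            edges.append((stack[-1], next_id, tok[1]))
            stack.append(next_id)
        else:
            stack.pop()
    if not edges:
        raise TreeError("cannot build a tree from an empty Euler string")
    tree = LabeledTree.from_edges(edges)
    if tag is not EPSILON:
        # positions survive preorder renumbering because we numbered in DFS order
        tag = int(tag)
    return tree, tag


def recanonicalize(es: EulerString) -> EulerString:
    """Canonical form of an arbitrary (ordered) Euler string under unordered
    semantics: parse, then canonicalize the resulting tree."""
    tree, tag = tree_from_euler(es)
    sub = UnorderedSubtree(1, tag, frozenset(tree.ch(1)))
    return canonicalize_unordered(tree, sub)
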