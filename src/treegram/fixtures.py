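"""Reference inputs and random generators used in experiments and tests.

* :func:`fig5` -- the 6-vertex tree whose edges (1,2), (1,3), (1,6), (3,4),
  (3,5) carry labels a, c, b, a, b: a root with an a-edge, a b-edge, and a
  c-edge whose lower endpoint again carries an a-edge and a b-edge.  Treated
  as an ordered tree its minimum simple-EOTG nonterminal count is 7; as an
  unordered tree the two isomorphic {a-child, b-child} subtrees merge and the
  minimum drops to 6.

* :func:`type_a` -- paths of ``n`` vertices, every edge labeled ``a``
  (maximum degree two).

* :func:`type_b` -- height-two trees with labels a and b, parameterized by
  branching: a root with ``degree - 1`` children, each bearing one leaf
  child, labels alternating between the levels.  (The exact topology used in
  the original experiments is approximated; nothing downstream depends on
  it.)

* :func:`abcabcab` -- the worked string example.

* :func:`random_tree` / :func:`random_string` -- seeded generators for
  property tests: uniform random attachment, labels drawn uniformly from a
  small alphabet, matching the scale of the artificial experiments (trees of
  up to a few dozen vertices, alphabets of 2-5 letters).
"""

from __future__ import annotations

import numpy as np

from .tree import LabeledTree


def fig5() -> LabeledTree:
    return LabeledTree.from_edges(
        [(1, 2, "a"), (1, 3, "c"), (1, 6, "b"), (3, 4, "a"), (3, 5, "b")]
    )


def type_a(n: int) -> LabeledTree:
    """Path with ``n`` vertices, all edges labeled ``a``."""
    if n < 2:
        raise ValueError("a Type A tree needs at least 2 vertices")
    return LabeledTree.from_edges([(i, i + 1, "a") for i in range(1, n)])


def type_b(degree: int) -> LabeledTree:
    """Height-two tree: a root with ``degree - 1`` children, each bearing one
    leaf child; edge labels alternate a/b between levels."""
    if degree < 2:
        raise ValueError("a Type B tree needs degree >= 2")
    edges = []
    nxt = 2
    for i in range(degree - 1):
        mid = nxt
        edges.append((1, mid, "a" if i % 2 == 0 else "b"))
        nxt += 1
        edges.append((mid, nxt, "b" if i % 2 == 0 else "a"))
        nxt += 1
    return LabeledTree.from_edges(edges)


def abcabcab() -> str:
    return "abcabcab"


def random_tree(
    n_vertices: int,
    labels: tuple[str, ...] = ("a", "b"),
    rng: np.random.Generator | int | None = None,
) -> LabeledTree:
    """Uniform random-attachment tree: vertex ``v`` attaches to a uniformly
    chosen earlier vertex with a uniformly chosen edge label."""
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    rng = np.random.default_rng(rng)
    edges = []
    for v in range(2, n_vertices + 1):
        p = int(rng.integers(1, v))
        lab = labels[int(rng.integers(0, len(labels)))]
        edges.append((p, v, lab))
    return LabeledTree.from_edges(edges)


def random_string(
    n: int,
    alphabet: str = "ab",
    rng: np.random.Generator | int | None = None,
) -> str:
    rng = np.random.default_rng(rng)
    return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))


NAMES = ("fig5", "type_a", "type_b", "abcabcab")


def get(name: str, n: int | None = None, degree: int | None = None):
    """Fixture lookup by name (CLI entry point)."""
    if name == "fig5":
        return fig5()
    if name == "type_a":
        if n is None:
            raise ValueError("type_a needs --n")
        return type_a(n)
    if name == "type_b":
        if degree is None:
            raise ValueError("type_b needs --degree")
        return type_b(degree)
    if name == "abcabcab":
        return abcabcab()
    raise ValueError(f"unknown fixture {name!r}; choose from {NAMES}")
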