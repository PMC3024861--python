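"""Independent brute-force oracles for the test suite.

Everything here works on explicit nested-tuple tree representations and
exhaustive search, deliberately sharing no code with the package's candidate
enumeration or IP path:

* a tree (forest under its root) is ``((label, child), ...)`` where ``child``
  is again a forest, ``()`` for a leaf, or the marker ``"TAG"`` for a tag;
* divisions are generated directly on these structures;
* the minimum grammar size is found by depth-first search over which
  isomorphism classes to admit, with branch-and-bound pruning.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

TAG = "TAG"


# -- representation helpers -------------------------------------------------

def rep_from_tree(tree) -> tuple:
    """Nested-tuple forest of a LabeledTree (duck-typed: ch / label)."""

    def forest(v):
        return tuple((tree.label(c), forest(c)) for c in tree.ch(v))

    return forest(tree.root)


def tree_from_rep(rep):
    """Forest representation -> edge list (for feeding the implementation)."""
    edges = []
    counter = [1]

    def walk(parent, forest):
        for lab, child in forest:
            counter[0] += 1
            v = counter[0]
            edges.append((parent, v, lab))
            if child not in ((), TAG):
                walk(v, child)

    walk(1, rep)
    return edges


def count_tags(rep) -> int:
    if rep in ((), TAG):
        return 1 if rep == TAG else 0
    return sum(count_tags(child) for _, child in rep)


def n_edges(rep) -> int:
    if rep in ((), TAG):
        return 0
    return sum(1 + n_edges(child) for _, child in rep)


def canon(rep):
    """Canonical form under unordered isomorphism: recursively sort edges,
    tag-carrying edge first."""
    if rep in ((), TAG):
        return rep
    edges = [(lab, canon(child)) for lab, child in rep]
    tagged = [e for e in edges if count_tags(e[1]) or e[1] == TAG]
    # any fixed total order works; repr avoids comparing TAG with tuples
    rest = sorted((e for e in edges if e not in tagged), key=repr)
    return tuple(tagged + rest)


def iso_unordered(r1, r2) -> bool:
    """Backtracking unordered-isomorphism test (tries all edge matchings)."""
    if r1 in ((), TAG) or r2 in ((), TAG):
        return r1 == r2
    if len(r1) != len(r2):
        return False
    if not r1:
        return True
    (lab, child), rest = r1[0], r1[1:]
    for i, (lab2, child2) in enumerate(r2):
        if lab == lab2 and iso_unordered(child, child2):
            if iso_unordered(rest, r2[:i] + r2[i + 1 :]):
                return True
    return False


# -- divisions --------------------------------------------------------------

def _vertical_divisions(rep):
    """All (upper, lower) pairs from tagging one internal vertex."""
    out = []

    def replace_at(forest, path, new_child):
        lab, child = forest[path[0]]
        if len(path) == 1:
            edge = (lab, new_child)
        else:
            edge = (lab, replace_at(child, path[1:], new_child))
        return forest[: path[0]] + (edge,) + forest[path[0] + 1 :]

    def walk(forest, path):
        for i, (lab, child) in enumerate(forest):
            if child in ((), TAG):
                continue
            upper = replace_at(rep, path + [i], TAG)
            if count_tags(upper) == 1:  # the original tag must go below
                out.append((upper, child))
            walk(child, path + [i])

    walk(rep, [])
    return out


def divisions_ordered(rep):
    """All legal (left, right) division results of an ordered tree."""
    out = [(rep[:i], rep[i:]) for i in range(1, len(rep))]
    out.extend(_vertical_divisions(rep))
    return out


def divisions_unordered(rep):
    """All legal division results of an unordered tree; horizontal splits are
    unordered subset pairs, deduplicated by canonical forms."""
    seen = set()
    out = []
    idx = range(len(rep))
    for r in range(1, len(rep)):
        for left_ix in combinations(idx, r):
            left = tuple(rep[i] for i in left_ix)
            right = tuple(rep[i] for i in idx if i not in left_ix)
            key = frozenset((canon(left), canon(right)))
            if key not in seen:
                seen.add(key)
                out.append((left, right))
    out.extend(_vertical_divisions(rep))
    return out


# -- minimum grammar search -------------------------------------------------

def brute_min_tree_grammar(rep, ordered: bool, force_tagged: bool = True) -> int:
    """Minimum number of nonterminal classes in a simple tree grammar
    generating exactly ``rep``, by exhaustive search over class choices."""
    key = (lambda r: r) if ordered else canon
    divide = divisions_ordered if ordered else divisions_unordered

    # constraint (1): single untagged leaf edges; tagged internal edges
    forced = set()

    def collect(forest):
        for lab, child in forest:
            if child == ():
                forced.add(key(((lab, ()),)))
            else:
                if force_tagged:
                    forced.add(key(((lab, TAG),)))
                collect(child)

    collect(rep)

    reps: dict = {}  # class key -> representative
    div_memo: dict = {}

    def class_divisions(k):
        if k not in div_memo:
            opts = []
            for left, right in divide(reps[k]):
                lk, rk = key(left), key(right)
                reps.setdefault(lk, left)
                reps.setdefault(rk, right)
                opts.append((lk, rk))
            div_memo[k] = sorted(set(opts), key=repr)
        return div_memo[k]

    root_key = key(rep)
    reps[root_key] = rep
    best = [float("inf")]

    def rec(stack, used):
        if len(used) >= best[0]:
            return
        if not stack:
            best[0] = len(used)
            return
        k = stack[-1]
        rest = stack[:-1]
        for lk, rk in class_divisions(k):
            new = [c for c in (lk, rk) if c not in used]
            nxt = rest + [c for c in dict.fromkeys(new) if n_edges(reps[c]) > 1]
            rec(nxt, used | set(new))

    init_used = forced | {root_key}
    init_stack = [root_key] if n_edges(rep) > 1 else []
    rec(init_stack, init_used)
    return int(best[0])


def brute_min_cfg(s: str) -> int:
    """Minimum nonterminal count of a simple CFG generating exactly ``s``,
    by exhaustive search over admitted distinct substrings."""
    subs = {s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1)}
    forced = set(s) | {s}
    free = sorted(subs - forced)

    def valid(chosen: frozenset) -> bool:
        for u in chosen:
            if len(u) == 1:
                continue
            if not any(
                u[:k] in chosen and u[k:] in chosen for k in range(1, len(u))
            ):
                return False
        return True

    base = frozenset(forced)
    for extra in range(len(free) + 1):
        for combo in combinations(free, extra):
            cand = base | frozenset(combo)
            if valid(cand):
                return len(cand)
    raise AssertionError("unreachable: the full substring set is always valid")


# -- exhaustive small-tree generation ----------------------------------------

def all_forests(e: int, labels=("a", "b")):
    """All ordered forests with exactly ``e`` edges over the label alphabet."""
    if e == 0:
        yield ()
        return
    for first in range(1, e + 1):
        for lab in labels:
            for child in all_forests(first - 1, labels):
                for rest in all_forests(e - first, labels):
                    yield ((lab, child),) + rest
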