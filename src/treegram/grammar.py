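"""Explicit simple grammars: reconstruction from IP solutions, counting,
round-trip verification, and serialization.

Nonterminals are *content-addressed*: the key of a nonterminal is the
substring (strings) or the canonical Euler-string text (trees) it generates,
so nonterminals generating the same object merge by construction and rule
merging is order-independent.

Two size metrics are reported:

* ``nonterminal_count`` -- distinct binary-rule left-hand sides plus distinct
  terminal classes used (tagged and untagged edges of the same label are
  distinct classes); this is the quantity the IP minimizes;
* ``rhs_size`` -- total letters on rule right-hand sides (the alternative
  grammar-size metric).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

from .tree import (
    EPSILON,
    EulerString,
    LabeledTree,
    OrderedSubtree,
    TAG_TOKEN,
    UnorderedSubtree,
    canonicalize_unordered,
    euler_string,
    recanonicalize,
)

GrammarMode = Literal["string", "ordered", "unordered"]

#: rule kinds: R1u/R1t terminal tree edges, R2 horizontal, R3 vertical,
#: CFG1/CFG2 string terminal/binary.
TERMINAL_KINDS = ("R1u", "R1t", "CFG1")
BINARY_KINDS = ("R2", "R3", "CFG2")


class GrammarError(ValueError):
    pass


class InconsistentSolutionError(GrammarError):
    """An active non-base candidate admits no usable division."""


@dataclass(frozen=True)
class Rule:
    lhs: str
    kind: str
    rhs: tuple[str, ...]

    def __post_init__(self):
        if self.kind in TERMINAL_KINDS and len(self.rhs) != 1:
            raise GrammarError(f"terminal rule needs one symbol: {self!r}")
        if self.kind in BINARY_KINDS and len(self.rhs) != 2:
            raise GrammarError(f"binary rule needs two symbols: {self!r}")
        if self.kind not in TERMINAL_KINDS + BINARY_KINDS:
            raise GrammarError(f"unknown rule kind {self.kind!r}")


@dataclass
class Grammar:
    """A simple grammar with its derivation of the input.

    ``derivation`` is the full parse tree: nested ``{"key": ..., "children":
    [...]}`` nodes, one node per expansion (shared nonterminals appear once
    per occurrence).
    """

    mode: GrammarMode
    terminals: tuple[str, ...]
    start: str
    rules: tuple[Rule, ...]
    derivation: dict | None = None

    def __post_init__(self):
        by_lhs: dict[str, Rule] = {}
        for r in self.rules:
            if r.lhs in by_lhs:
                raise GrammarError(f"two rules for nonterminal {r.lhs!r}")
            by_lhs[r.lhs] = r
        self._by_lhs = by_lhs
        if self.start not in by_lhs:
            raise GrammarError(f"start symbol {self.start!r} has no rule")

    def rule_for(self, key: str) -> Rule:
        try:
            return self._by_lhs[key]
        except KeyError:
            raise GrammarError(f"unbound nonterminal {key!r}") from None

    @property
    def binary_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.kind in BINARY_KINDS]

    @property
    def terminal_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.kind in TERMINAL_KINDS]


def nonterminal_count(g: Grammar) -> int:
    """Distinct binary-rule LHSs plus distinct terminal classes used."""
    return len({r.lhs for r in g.binary_rules}) + len(
        {r.lhs for r in g.terminal_rules}
    )


def rhs_size(g: Grammar) -> int:
    """Total letters on rule right-hand sides."""
    return sum(len(r.rhs) for r in g.rules)


# -- reconstruction from an IP solution ------------------------------------

_PREF = {"H": 0, "S": 0, "V": 1}


def _div_sort_key(d):
    # H before V; then smallest split index / lexicographically smallest
    # subset.  Mixed where-types never meet: the preference rank ties first.
    return (_PREF[d.kind], d.where)


class _Builder:
    """Accumulates content-addressed rules plus a derivation tree while
    walking candidate indices top-down."""

    def __init__(self, instance):
        self.inst = instance
        self.rule_of: dict[str, Rule] = {}
        self.order: list[str] = []

    def key(self, s) -> str:
        return self.inst.key_of[s]

    def add_rule(self, rule: Rule) -> None:
        old = self.rule_of.get(rule.lhs)
        if old is None:
            self.rule_of[rule.lhs] = rule
            self.order.append(rule.lhs)
        elif old != rule:
            raise InconsistentSolutionError(
                f"conflicting rules for {rule.lhs!r}: {old!r} vs {rule!r}"
            )

    def terminal_rule(self, s) -> Rule:
        inst = self.inst
        if inst.kind == "cfg":
            (i, _) = s
            return Rule(self.key(s), "CFG1", (inst.source[i - 1],))
        label = inst.source.label(_base_child(s))
        kind = "R1t" if s.tag is not EPSILON else "R1u"
        return Rule(self.key(s), kind, (label,))

    def binary_kind(self, d) -> str:
        if self.inst.kind == "cfg":
            return "CFG2"
        return "R2" if d.kind == "H" else "R3"

    def binary_rhs(self, d, lk: str, rk: str) -> tuple[str, str]:
        # unordered root composition is commutative: normalize so isomorphic
        # subtrees always merge onto one rule
        if self.inst.kind == "seutg" and d.kind == "H":
            return tuple(sorted((lk, rk)))
        return (lk, rk)

    def expand(self, s, chooser) -> dict:
        """Expand index ``s``; ``chooser(s)`` returns the chosen division or
        None for a base index."""
        d = chooser(s)
        if d is None:
            self.add_rule(self.terminal_rule(s))
            return {"key": self.key(s)}
        rule = Rule(
            self.key(s),
            self.binary_kind(d),
            self.binary_rhs(d, self.key(d.left), self.key(d.right)),
        )
        self.add_rule(rule)
        return {
            "key": self.key(s),
            "children": [
                self.expand(d.left, chooser),
                self.expand(d.right, chooser),
            ],
        }

    def grammar(self, mode: GrammarMode, start: str, derivation: dict) -> Grammar:
        inst = self.inst
        if inst.kind == "cfg":
            terminals = tuple(sorted(set(inst.source)))
        else:
            terminals = tuple(sorted(set(inst.source.label_multiset())))
        rules = tuple(self.rule_of[k] for k in self.order)
        return Grammar(mode, terminals, start, rules, derivation)


def _base_child(s) -> int:
    if isinstance(s, OrderedSubtree):
        return s.h
    (c,) = s.children
    return c


def extract_grammar(instance, result) -> Grammar:
    """Reconstruct a grammar from an optimal solution with the root generated.

    The derivation is rebuilt top-down from the solution's active nonterminal
    classes: for each needed subtree the first division (horizontal before
    vertical, then smallest split index / lexicographically smallest subset)
    whose two parts lie in active classes and are themselves derivable is
    chosen.  This makes the output deterministic for a fixed solver solution
    while staying faithful to it.  Terminal rules for all forced base edges
    are included (the IP counts their classes whether or not the derivation
    reuses them).
    """
    if result.status != "optimal":
        raise GrammarError(f"cannot extract from a {result.status} solve")
    root_val = result.value(instance, instance.x[instance.root])
    if root_val != 1:
        raise GrammarError("solution does not generate the input (root = 0)")
    active = result.active_classes(instance)
    key_of = instance.key_of
    base_keys = {key_of[s] for s in instance.base_set}

    derivable_memo: dict[str, bool] = {}
    first_index: dict[str, object] = {}
    for s in instance.x:  # insertion order = discovery order
        first_index.setdefault(key_of[s], s)

    def derivable(u: str) -> bool:
        if u in derivable_memo:
            return derivable_memo[u]
        if u not in active:
            derivable_memo[u] = False
            return False
        if u in base_keys:
            derivable_memo[u] = True
            return True
        ok = False
        for d in sorted(instance.by_parent.get(first_index[u], []), key=_div_sort_key):
            if derivable(key_of[d.left]) and derivable(key_of[d.right]):
                ok = True
                break
        derivable_memo[u] = ok
        return ok

    builder = _Builder(instance)
    chosen_rhs: dict[str, tuple[str, str]] = {}

    def chooser(s):
        if s in instance.base_set:
            return None
        u = key_of[s]
        want = chosen_rhs.get(u)
        for d in sorted(instance.by_parent[s], key=_div_sort_key):
            lk, rk = key_of[d.left], key_of[d.right]
            norm = builder.binary_rhs(d, lk, rk)
            if want is not None and (d.kind,) + norm != want:
                continue
            if lk in active and rk in active and derivable(lk) and derivable(rk):
                chosen_rhs[u] = (d.kind,) + norm
                return d
        raise InconsistentSolutionError(
            f"no usable division for active candidate {s!r}"
        )

    derivation = builder.expand(instance.root, chooser)
    # constraint (1) also charges forced-but-unused terminal classes to m
    for s in instance.forced:
        builder.add_rule(builder.terminal_rule(s))
    mode = {"cfg": "string", "seotg": "ordered", "seutg": "unordered"}[instance.kind]
    return builder.grammar(mode, key_of[instance.root], derivation)


# -- verification ----------------------------------------------------------

def _expand_tokens(g: Grammar, key: str, memo: dict) -> tuple:
    if key in memo:
        return memo[key]
    rule = g.rule_for(key)
    if rule.kind == "CFG1":
        out: tuple = (rule.rhs[0],)
    elif rule.kind == "CFG2":
        out = _expand_tokens(g, rule.rhs[0], memo) + _expand_tokens(
            g, rule.rhs[1], memo
        )
    elif rule.kind == "R1u":
        out = (("o", rule.rhs[0]), ("c", rule.rhs[0]))
    elif rule.kind == "R1t":
        out = (("o", rule.rhs[0]), TAG_TOKEN, ("c", rule.rhs[0]))
    elif rule.kind == "R2":
        out = _expand_tokens(g, rule.rhs[0], memo) + _expand_tokens(
            g, rule.rhs[1], memo
        )
    else:  # R3: attach the lower tree at the upper tree's tag
        upper = _expand_tokens(g, rule.rhs[0], memo)
        lower = _expand_tokens(g, rule.rhs[1], memo)
        if upper.count(TAG_TOKEN) != 1:
            raise GrammarError(f"vertical rule with untagged upper part: {rule!r}")
        i = upper.index(TAG_TOKEN)
        out = upper[:i] + lower + upper[i + 1 :]
    memo[key] = out
    return out


def expand(g: Grammar, key: str | None = None) -> Union[str, EulerString]:
    """Fully expand a nonterminal (default: the start symbol)."""
    key = g.start if key is None else key
    toks = _expand_tokens(g, key, {})
    if g.mode == "string":
        return "".join(toks)
    return EulerString(toks)


def verify_roundtrip(g: Grammar, source: Union[str, LabeledTree]) -> bool:
    """Does the grammar regenerate exactly the input?

    Every nonterminal must expand to its own key (up to canonical reordering
    in unordered mode), and the start symbol to the input string / the
    input's (canonical) Euler string.
    """
    memo: dict = {}
    try:
        for rule in g.rules:
            got = _expand_tokens(g, rule.lhs, memo)
            if g.mode == "string":
                if "".join(got) != rule.lhs:
                    return False
            elif g.mode == "ordered":
                if EulerString(got) != EulerString.from_text(rule.lhs):
                    return False
            else:
                if recanonicalize(EulerString(got)) != EulerString.from_text(rule.lhs):
                    return False
        start = _expand_tokens(g, g.start, memo)
    except GrammarError:
        return False
    if g.mode == "string":
        return "".join(start) == source
    if g.mode == "ordered":
        return EulerString(start) == euler_string(source, source.whole_ordered())
    target = canonicalize_unordered(source, source.whole_unordered())
    return recanonicalize(EulerString(start)) == target


# -- serialization ---------------------------------------------------------

def to_dict(g: Grammar) -> dict:
    return {
        "format": "treegram-grammar/1",
        "mode": g.mode,
        "terminals": list(g.terminals),
        "start": g.start,
        "rules": [
            {"lhs": r.lhs, "kind": r.kind, "rhs": list(r.rhs)}
            for r in sorted(g.rules, key=lambda r: (r.kind, r.lhs))
        ],
        "metrics": {"nonterminals": nonterminal_count(g), "rhs_size": rhs_size(g)},
        "derivation": g.derivation,
    }


def from_dict(doc: dict) -> Grammar:
    if doc.get("format") != "treegram-grammar/1":
        raise GrammarError(f"unknown grammar document format {doc.get('format')!r}")
    rules = tuple(
        Rule(r["lhs"], r["kind"], tuple(r["rhs"])) for r in doc["rules"]
    )
    return Grammar(
        doc["mode"], tuple(doc["terminals"]), doc["start"], rules,
        doc.get("derivation"),
    )


def serialize(g: Grammar) -> str:
    """Loss-free JSON text with stable rule ordering (diffable)."""
    return json.dumps(to_dict(g), indent=1, sort_keys=False)


def deserialize(text: str) -> Grammar:
    return from_dict(json.loads(text))
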