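"""TREE-BISECTION baseline: balanced recursive division of an ordered tree.

A polynomial-time alternative to the exact IP: every subtree with at least
two edges is divided by the legal horizontal or vertical division whose two
parts have the most similar *edge counts*; ties prefer horizontal divisions,
then the smallest split index.  Recursion bottoms out at single edges.
Nonterminals are content-addressed by Euler string, so isomorphic subtrees
merge exactly as in the IP-derived grammars, and the result always
regenerates the input.  The grammar it produces is never smaller than the IP
minimum (which is exact); the gap is what the IP buys.
"""

from __future__ import annotations

from .candidates import ordered_divisions
from .grammar import Grammar, Rule, _div_sort_key
from .tree import EPSILON, LabeledTree, OrderedSubtree, euler_string


def tree_bisection(tree: LabeledTree) -> Grammar:
    """Build a simple EOTG for ``tree`` by balanced bisection."""
    rule_of: dict[str, Rule] = {}
    order: list[str] = []
    chosen: dict[str, tuple] = {}

    def add(rule: Rule) -> None:
        if rule.lhs not in rule_of:
            rule_of[rule.lhs] = rule
            order.append(rule.lhs)

    def key(sub: OrderedSubtree) -> str:
        return euler_string(tree, sub).text

    def expand(sub: OrderedSubtree) -> dict:
        u = key(sub)
        if tree.is_base_ordered(sub):
            kind = "R1t" if sub.tag is not EPSILON else "R1u"
            add(Rule(u, kind, (tree.label(sub.h),)))
            return {"key": u}
        divs = ordered_divisions(tree, sub)
        want = chosen.get(u)
        if want is not None:
            # an isomorphic subtree was already divided: reuse its rule
            pick = next(
                d
                for d in sorted(divs, key=_div_sort_key)
                if (d.kind, key(d.left), key(d.right)) == want
            )
        else:
            pick = min(
                divs,
                key=lambda d: (
                    abs(tree.subtree_edges(d.left) - tree.subtree_edges(d.right)),
                ) + _div_sort_key(d),
            )
            chosen[u] = (pick.kind, key(pick.left), key(pick.right))
        add(
            Rule(
                u,
                "R2" if pick.kind == "H" else "R3",
                (key(pick.left), key(pick.right)),
            )
        )
        return {
            "key": u,
            "children": [expand(pick.left), expand(pick.right)],
        }

    derivation = expand(tree.whole_ordered())
    return Grammar(
        mode="ordered",
        terminals=tuple(sorted(set(tree.label_multiset()))),
        start=key(tree.whole_ordered()),
        rules=tuple(rule_of[k] for k in order),
        derivation=derivation,
    )
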