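"""Grammar reconstruction, counting, round-trip verification, serialization."""

import numpy as np
import pytest

from treegram import (
    Grammar,
    Rule,
    build_ordered_ip,
    deserialize,
    extract_grammar,
    find_minimum_m,
    fixtures,
    nonterminal_count,
    rhs_size,
    serialize,
    solve,
    verify_roundtrip,
)
from treegram.grammar import GrammarError, expand, to_dict
from treegram.tree import EulerString


def _minimum_grammar(source, mode):
    m, inst, res = find_minimum_m(source, mode)
    return m, extract_grammar(inst, res)


class TestExtraction:
    def test_ordered_example_has_four_binary_rules(self, fig5):
        m, g = _minimum_grammar(fig5, "seotg")
        assert m == 7
        assert len(g.binary_rules) == 4
        # the 2-child subtree decomposes into its a- and b-edges in every
        # optimal grammar, and the c-subtree via its tagged c-edge
        rules = {(r.lhs, r.rhs) for r in g.binary_rules}
        assert ("a /a b /b", ("a /a", "b /b")) in rules
        assert ("c a /a b /b /c", ("c * /c", "a /a b /b")) in rules

    def test_unordered_example_merges_isomorphic_subtrees(self, fig5):
        m, g = _minimum_grammar(fig5, "seutg")
        assert m == 6
        # the {a-child, b-child} subtree occurs twice in the derivation but
        # is one nonterminal
        counts = {}
        stack = [g.derivation]
        while stack:
            node = stack.pop()
            counts[node["key"]] = counts.get(node["key"], 0) + 1
            stack.extend(node.get("children", ()))
        assert counts["a /a b /b"] == 2
        assert sum(1 for r in g.rules if r.lhs == "a /a b /b") == 1

    def test_single_edge_tree_has_one_terminal_rule(self, single_edge):
        m, g = _minimum_grammar(single_edge, "seotg")
        assert m == 1
        assert len(g.rules) == 1
        assert g.rules[0].kind == "R1u" and g.rules[0].rhs == ("a",)

    def test_extraction_requires_optimal_generating_solution(self, fig5):
        inst = build_ordered_ip(fig5, m=6)
        res = solve(inst)  # optimal but root = 0
        with pytest.raises(GrammarError):
            extract_grammar(inst, res)

    def test_string_grammar_kinds(self):
        _, g = _minimum_grammar("abab", "cfg")
        assert {r.kind for r in g.terminal_rules} == {"CFG1"}
        assert {r.kind for r in g.binary_rules} == {"CFG2"}


class TestCounting:
    def test_counts_match_search_minimum_on_fixtures(self, fig5, path3):
        for source, mode in [
            (fig5, "seotg"),
            (fig5, "seutg"),
            (path3, "seotg"),
            (fixtures.type_a(7), "seutg"),
            ("abcabcab", "cfg"),
            ("ab", "cfg"),
        ]:
            m, g = _minimum_grammar(source, mode)
            assert nonterminal_count(g) == m

    def test_rhs_size_counts_letters(self, single_edge):
        _, g = _minimum_grammar(single_edge, "seotg")
        assert rhs_size(g) == 1
        _, g = _minimum_grammar("ab", "cfg")
        # a, b, and S -> AB
        assert rhs_size(g) == 4

    def test_tagged_and_untagged_edges_are_distinct_classes(self, path3):
        m, g = _minimum_grammar(path3, "seotg")
        # path of two a-edges: classes a/a untagged leaf, a*-tagged, whole
        assert m == 3
        kinds = sorted(r.kind for r in g.rules)
        assert kinds == ["R1t", "R1u", "R3"]


class TestRoundtrip:
    def test_every_extracted_grammar_regenerates_its_input(self, fig5):
        rng = np.random.default_rng(17)
        cases = [(fig5, "seotg"), (fig5, "seutg"), ("abcabcab", "cfg")]
        for _ in range(6):
            t = fixtures.random_tree(int(rng.integers(2, 9)), ("a", "b"), rng)
            cases.append((t, "seotg"))
            cases.append((t, "seutg"))
        for source, mode in cases:
            _, g = _minimum_grammar(source, mode)
            assert verify_roundtrip(g, source)

    def test_deleting_a_binary_rule_breaks_regeneration(self, fig5):
        _, g = _minimum_grammar(fig5, "seotg")
        pruned = Grammar(
            g.mode, g.terminals, g.start,
            tuple(r for r in g.rules if r != g.binary_rules[-1]),
            g.derivation,
        )
        assert not verify_roundtrip(pruned, fig5)

    def test_wrong_input_rejected(self, fig5, path3):
        _, g = _minimum_grammar(fig5, "seotg")
        assert not verify_roundtrip(g, path3)

    def test_expand_start_symbol(self, fig5):
        _, g = _minimum_grammar(fig5, "seotg")
        assert expand(g) == EulerString.from_text("a /a c a /a b /b /c b /b")

    def test_derivation_leaves_conserve_edge_multiset(self, fig5):
        for mode in ("seotg", "seutg"):
            _, g = _minimum_grammar(fig5, mode)
            leaf_labels = []
            stack = [g.derivation]
            while stack:
                node = stack.pop()
                kids = node.get("children")
                if kids:
                    stack.extend(kids)
                else:
                    es = EulerString.from_text(node["key"])
                    assert es.n_edges == 1
                    leaf_labels.extend(es.labels())
            assert sorted(leaf_labels) == fig5.label_multiset()


class TestSerialization:
    def test_json_round_trip_is_lossless(self, fig5):
        for source, mode in [(fig5, "seotg"), (fig5, "seutg"), ("abab", "cfg")]:
            _, g = _minimum_grammar(source, mode)
            again = deserialize(serialize(g))
            assert to_dict(again) == to_dict(g)
            assert nonterminal_count(again) == nonterminal_count(g)

    def test_unknown_format_rejected(self):
        with pytest.raises(GrammarError):
            deserialize('{"format": "nope"}')

    def test_duplicate_rules_rejected(self):
        with pytest.raises(GrammarError, match="two rules"):
            Grammar(
                "string", ("a",), "a",
                (Rule("a", "CFG1", ("a",)), Rule("a", "CFG1", ("a",))),
            )
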