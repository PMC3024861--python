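"""Tree model: preorder invariants, Euler strings, unordered canonicalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treegram import (
    EPSILON,
    EulerString,
    LabeledTree,
    OrderedSubtree,
    TreeError,
    UnorderedSubtree,
    canonicalize_unordered,
    euler_string,
    fixtures,
    tree_from_euler,
)
from treegram.tree import recanonicalize

from .oracles import canon, iso_unordered, rep_from_tree


class TestLabeledTree:
    def test_preorder_renumbering_and_original_ids(self):
        t = LabeledTree.from_edges([("r", "x", "a"), ("x", "y", "b"), ("r", "z", "c")])
        assert t.root == 1
        assert list(t.preorder()) == [1, 2, 3, 4]
        assert t.original_ids[1] == "r"
        # sibling order preserved: x (with child y) before z
        assert t.ch(1) == (2, 4)
        assert t.label(2) == "a" and t.label(3) == "b" and t.label(4) == "c"

    def test_structural_invariants(self, fig5):
        assert fig5.n_vertices == 6 and fig5.n_edges == 5
        assert fig5.ch(1) == (2, 3, 6) and fig5.ch(3) == (4, 5)
        assert fig5.lch(1) == 2 and fig5.rch(1) == 6
        assert fig5.an(5) == {1, 3}
        assert 5 not in fig5.an(5)
        assert fig5.label_multiset() == ["a", "a", "b", "b", "c"]

    @pytest.mark.parametrize(
        "edges, msg",
        [
            ([(1, 2, "a"), (3, 4, "b")], "root"),
            ([(1, 2, "a"), (2, 1, "b")], "root"),
            ([(1, 2, "a"), (1, 2, "b")], "two parents"),
            ([], "at least one edge"),
            ([(1, 2, "bad label")], "label"),
        ],
    )
    def test_malformed_inputs_rejected(self, edges, msg):
        with pytest.raises(TreeError, match=msg):
            LabeledTree.from_edges(edges)

    def test_subtree_validation(self, fig5):
        with pytest.raises(TreeError):
            fig5.validate_ordered(OrderedSubtree(1, EPSILON, 3, 2))  # h right of k
        with pytest.raises(TreeError):
            fig5.validate_ordered(OrderedSubtree(1, 5, 2, 2))  # tag outside span
        with pytest.raises(TreeError):
            fig5.validate_unordered(UnorderedSubtree(1, EPSILON, frozenset()))
        fig5.validate_ordered(OrderedSubtree(1, 4, 3, 6))  # tag below span child


class TestEulerString:
    def test_single_edge_untagged(self, single_edge):
        es = euler_string(single_edge, OrderedSubtree(1, EPSILON, 2, 2))
        assert es.text == "a /a"

    def test_single_edge_tagged_emits_tag_between_open_and_close(self, path3):
        # the tagged edge with label A serializes as A, tag, A-close
        es = euler_string(path3, OrderedSubtree(1, 2, 2, 2))
        assert es.text == "a * /a"

    def test_whole_example_tree(self, fig5):
        es = euler_string(fig5, fig5.whole_ordered())
        assert es.text == "a /a c a /a b /b /c b /b"

    def test_invalid_subtree_rejected(self, fig5):
        with pytest.raises(TreeError):
            euler_string(fig5, OrderedSubtree(3, EPSILON, 2, 2))

    def test_tag_count_at_most_one(self, fig5):
        for sub in [fig5.whole_ordered(), OrderedSubtree(1, 3, 2, 6)]:
            es = euler_string(fig5, sub)
            assert es.tokens.count(("x",)) == (0 if sub.tag is EPSILON else 1)

    def test_unbalanced_tokens_rejected(self):
        with pytest.raises(TreeError):
            EulerString((("o", "a"), ("c", "b")))

    def test_round_trip_parse_and_reserialize(self, fig5):
        for sub in [fig5.whole_ordered(), OrderedSubtree(1, 3, 2, 6),
                    OrderedSubtree(3, EPSILON, 4, 5)]:
            es = euler_string(fig5, sub)
            parsed, tag = tree_from_euler(es)
            again = euler_string(parsed, OrderedSubtree(1, tag, parsed.lch(1),
                                                        parsed.rch(1)))
            assert again == es

    def test_text_round_trip(self, fig5):
        es = euler_string(fig5, OrderedSubtree(1, 3, 2, 6))
        assert EulerString.from_text(es.text) == es


class TestEulerProperties:
    @staticmethod
    def _tree_from(attach):
        edges = []
        for idx, (p, lab) in enumerate(attach):
            edges.append((p % (idx + 1) + 1, idx + 2, lab))
        return LabeledTree.from_edges(sorted(edges, key=lambda e: e[0]))

    @given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from("abc")),
                    min_size=1, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_parse_reserialize_is_identity(self, attach):
        t = self._tree_from(attach)
        es = euler_string(t, t.whole_ordered())
        parsed, tag = tree_from_euler(es)
        assert tag is EPSILON
        again = euler_string(parsed, parsed.whole_ordered())
        assert again == es

    @given(st.lists(st.tuples(st.integers(0, 30), st.sampled_from("ab")),
                    min_size=1, max_size=10))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_canonicalization_idempotent_and_untagged(self, attach):
        t = self._tree_from(attach)
        es = canonicalize_unordered(t, t.whole_unordered())
        assert not es.has_tag
        assert recanonicalize(es) == es


class TestCanonicalizeUnordered:
    def test_children_serialized_in_sorted_order(self, fig5):
        # presented order is (a@2, c@3, b@6); canonical puts a, b, then c-subtree
        es = canonicalize_unordered(fig5, fig5.whole_unordered())
        assert es.text == "a /a b /b c a /a b /b /c"

    def test_tagged_child_first(self, fig5):
        es = canonicalize_unordered(fig5, UnorderedSubtree(1, 3, frozenset({2, 3, 6})))
        assert es.text == "c * /c a /a b /b"

    def test_idempotent(self, fig5):
        es = canonicalize_unordered(fig5, fig5.whole_unordered())
        assert recanonicalize(es) == es

    def test_matches_lexicographic_minimum_over_child_permutations(self, fig5):
        # brute force: minimum ordered Euler string over all sibling orders
        import itertools

        def all_orders(tree, v):
            if tree.is_leaf(v):
                yield ()
                return
            for perm in itertools.permutations(tree.ch(v)):
                for combo in itertools.product(
                    *(list(all_orders(tree, c)) for c in perm)
                ):
                    yield tuple(zip(perm, combo))

        def serialize(tree, arrangement):
            toks = []

            def emit(v, arr):
                toks.append(("o", tree.label(v)))
                for c, sub in arr:
                    emit(c, sub)
                toks.append(("c", tree.label(v)))

            for c, sub in arrangement:
                emit(c, sub)
            return tuple(toks)

        best = min(
            serialize(fig5, arr) for arr in all_orders(fig5, 1)
        )
        got = canonicalize_unordered(fig5, fig5.whole_unordered())
        assert got.tokens == best

    def test_agrees_with_brute_force_isomorphism_on_random_trees(self):
        """Equal canonical strings iff unordered-isomorphic (trees <= 12
        vertices, seeded sample)."""
        rng = np.random.default_rng(7)
        trees = [
            fixtures.random_tree(int(rng.integers(3, 13)), ("a", "b"), rng)
            for _ in range(24)
        ]
        reps = [rep_from_tree(t) for t in trees]
        keys = [
            canonicalize_unordered(t, t.whole_unordered()).text for t in trees
        ]
        for i in range(len(trees)):
            for j in range(i + 1, len(trees)):
                assert (keys[i] == keys[j]) == iso_unordered(reps[i], reps[j])

    def test_oracle_canon_agrees_with_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = fixtures.random_tree(int(rng.integers(2, 12)), ("a", "b"), rng)
            shuffled_edges = []
            for p in t.vertices():
                kids = list(t.ch(p))
                rng.shuffle(kids)
                shuffled_edges.extend((p, c, t.label(c)) for c in kids)
            # rebuild with shuffled sibling order; canonical key must not move
            from treegram import LabeledTree

            t2 = LabeledTree.from_edges(sorted(shuffled_edges, key=lambda e: e[0]))
            k1 = canonicalize_unordered(t, t.whole_unordered()).text
            k2 = canonicalize_unordered(t2, t2.whole_unordered()).text
            assert k1 == k2
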