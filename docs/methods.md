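# Methods

## Model

A *simple CFG* restricts production rules to `A → a` and `A → BC`; its size
is the number of nonterminal symbols m (the count of `A → a` rules is fixed
by the alphabet actually used, so m is the meaningful part).  The tree
analogues replace the edge carrying a nonterminal by: a terminal edge
(R1u untagged, R1t tagged), a two-part root composition (R2, horizontal
division), or a vertical stacking at a tag (R3).  A *tag* is a distinguished
vertex, at most one per tree, where another tree may be attached at its
root; in Euler strings the tagged edge with label `A` serializes as
`A * /A`.

Equality of Euler strings characterizes isomorphism of ordered subtrees.
For unordered trees, the canonical form sorts every vertex's children
recursively by their canonical edge fragments, placing a tag-carrying child
first.  Sorting by *labels alone* would be ambiguous whenever two children
share a label but differ below; the recursive (subtree-aware) key is
required for canonical equality to coincide with unordered isomorphism, and
the test suite checks that coincidence against a brute-force
all-matchings isomorphism test on random trees up to 12 vertices.

## Candidates

Subtree candidates are generated top-down from the whole tree and closed
under division, rather than enumerating all index tuples; only indices that
can appear in a derivation become IP variables.  On the 6-vertex example
tree this yields 13 candidate nonterminals with 9 horizontal + 4 vertical
divisions (ordered) and 14 candidates with 12 + 4 (unordered), which are
exactly the candidate counts the worked example requires.  Base elements
are single untagged leaf edges and single tagged edges at internal
vertices; a tag at a leaf admits no attachment and is never generated.

A horizontal division of a *tagged* subtree keeps the tag on exactly the
side whose children contain it — the at-most-one-tag invariant forces this
reading.  A vertical division of a subtree tagged at `j` may only cut at a
strict ancestor of `j`; otherwise one part would carry two tags.  Unordered
horizontal splits are generated once per unordered subset pair `{C1, C2}`
(anchored on the smallest child); generating ordered pairs would
double-count.

Unordered enumeration grows with the number of child subsets, so it refuses
trees in which some vertex has more than `max_children` children
(default 16, configurable).  Exact unordered solving at such degrees is
impractical anyway: an unordered height-2 tree with root degree 8 already
takes ~2 minutes of branch-and-bound here, and wider roots grow
exponentially.

## Integer program

Constraint (5) is implemented as `Σ z ≤ m` although the problem statement
fixes the count to exactly m: with `≤`, feasibility is monotone in m and
any solution can be padded with idle classes up to equality, so the minimum
is unchanged; `budget_mode="eq"` switches to strict equality.  The
biconditional semantics of the division variables is relaxed to
`2y ≤ x_left + x_right` plus the coverage constraint `x ≤ Σ y`; coverage is
the only force pushing `y` up, so the relaxation preserves the optimum.

Constraint (1t) — forcing every single tagged internal edge to be generated
— is ON by default and exposed as a flag.  The two readings cannot differ on
the minimum: an edge into an internal vertex can only ever become a base
element as a tagged edge (its untagged single-child index still contains the
whole subtree below), so every complete derivation uses every tagged
internal-edge class anyway.

The minimize strategy performs one solve (root variable fixed to 1,
objective `min Σ z`); the probe strategy runs ascending feasibility probes
starting at the forced-terminal-class lower bound.  Monotonicity makes them
agree, and the suite asserts that they do.  The backend is HiGHS through
`scipy.optimize.milp`: exact, single-threaded, deterministic for a fixed
instance; it needs no random seed, and the `solver.seed` knob exists only to
honor the backend contract.  Time limits are reported as a distinct
`timeout` status, never conflated with infeasibility.

## Grammar reconstruction

Nonterminals are content-addressed by the substring / canonical Euler
string they generate, so identification of same-language nonterminals is
automatic.  The derivation is rebuilt top-down from the solution's active
classes; among the usable divisions of a subtree the preference order is
horizontal before vertical, then smallest split index / lexicographically
smallest subset.  The preference only fixes *which* co-optimal grammar is
printed — the count is preference-invariant, and several optimal grammars
usually exist (for the worked example, the pipeline deterministically
returns the left-right mirror of one of them).  Unordered root composition
is commutative, so unordered R2 right-hand sides are normalized to sorted
order; without this, two isomorphic subtrees whose subset splits enumerate
in opposite orders could not share one rule.

Terminal rules for *all* forced base classes are emitted, including ones
the derivation does not reuse, because the budget constraint charges their
classes to m either way; this keeps `nonterminal_count(extract(...))` equal
to the searched minimum on every input, which the suite asserts.

Verification expands every nonterminal and checks it reproduces its own key
(after re-canonicalization in unordered mode, since substituting a subtree
at a tag can change the canonical child order) and that the start symbol
reproduces the input exactly.

## TREE-BISECTION baseline

The baseline recursively applies the legal division minimizing the
*edge-count* difference of the two parts (the original formulation leaves
open whether vertices or edges are balanced; edge counts are used here, a
choice anyone comparing against other implementations should note), with
deterministic tie-breaking: horizontal first, then leftmost split.  Only
the dominance property — baseline size ≥ exact minimum — is guaranteed and
tested; exact baseline sizes depend on the tie-breaking details of any
particular implementation.

## Pattern extraction

A pattern is a nonterminal expanded at least twice in the derivation tree.
Occurrences are counted in the derivation, not in the rule set, and are
non-overlapping by construction: two nodes of the same class have equal
edge counts, so neither can be an ancestor of the other, hence
`occurrences × edges ≤ input edges` for every pattern (asserted).  Tagged
nonterminals are reported and flagged, since cores of branched structures
appear as tagged contexts.

## Synthetic data and fixtures

* `fig5` — the 6-vertex worked example, fixed.
* `type_a(n)` — a path of n vertices, all edges labeled `a`: the
  maximum-redundancy unary case (its minima follow an addition-chain-like
  pattern: 7 nonterminals at 11 vertices).
* `type_b(degree)` — height-two trees over labels {a, b}: a root with
  `degree − 1` children, each bearing one leaf child, labels alternating.
  This approximates the bounded-height family used in the original
  experiments, whose exact topology is not recoverable from the published
  description; no reference value is tied to it.
* `random_tree(n, labels, rng)` — uniform random attachment with uniform
  labels.  These trees have unbounded degree and geometric-ish depth; they
  exercise the combinatorics but are not a model of real glycans (real
  glycans are small, low-degree, and label-correlated), so passing property
  tests on them demonstrates correctness of the algorithms, not biological
  coverage.
* A hand-written synthetic KCF record exercises the glycan parser; real
  KEGG records are read from disk with the same code path (root at the
  reducing end, edge labels from the lower endpoint's sugar, deterministic
  first-seen letter assignment with the mapping emitted alongside).

## Problem sizes used by the suite

Exhaustive oracle equivalence (implementation vs. independent brute-force
search over derivations) runs over all strings of length ≤ 6 on {a, b} and
all ordered tree shapes with ≤ 3 edges under every {a, b} labeling, plus a
seeded sample of twelve 4–6-edge trees; the cross-mode and dominance
properties run on 50 random trees of ≤ 10 vertices.  These sizes keep the
whole suite under about a minute while covering every code path; the exact
solver itself has been exercised up to 21-vertex paths (~2.5 minutes) and
25-vertex height-two trees.  Unary paths beyond ~25 vertices take
branch-and-bound into hours — consistent with the original report that even
a commercial solver needed hours at 41–51 vertices — and are therefore not
part of any default run.

## Known limitations

* Single trees only: no forests, no cross-input motif mining, no cyclic
  structures.
* Vertex labels are not modeled (edges carry the alphabet).
* The unordered formulation is exponential in vertex degree by nature;
  the degree guard makes the refusal explicit instead of silent.
* KCF parsing assumes the reducing-end node is numbered 1 (the usual KEGG
  convention) and falls back to the smallest node id otherwise.
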