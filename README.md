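# treegram

Exact minimum grammar-based compression of strings and rooted edge-labeled
trees, by integer programming — with a balanced-bisection baseline and
repeated-subtree (motif) extraction for glycan-like tree structures.

## The problem

Grammar-based compression looks for a small grammar that generates one given
object and nothing else; the size of that grammar measures the object's
redundancy, and its reused rules expose repeated structure.  For a string
`s` the grammar is a *simple CFG* (rules `A → a` and `A → BC` only) and the
size is the number of nonterminal symbols *m*.  Finding the smallest such
grammar is NP-hard, so polynomial-time tools settle for approximations.
This package instead solves the problem *exactly*, for three input classes:

* **strings** over an arbitrary terminal alphabet (minimum simple CFG),
* **rooted ordered trees** with labeled edges (minimum simple *elementary
  ordered tree grammar*, SEOTG),
* **rooted unordered trees** (minimum simple *elementary unordered tree
  grammar*, SEUTG).

Tree grammars extend `A → BC` with two bisection rules: a **horizontal**
division splits a subtree at its root into two child spans (ordered) or
child subsets (unordered); a **vertical** division cuts at an internal
vertex `t`, leaving an upper part *tagged* at `t` (a marked attachment
point, at most one per tree) and the lower subtree rooted at `t`.  Subtrees
are identified up to isomorphism through their **Euler strings** — the
depth-first serialization with matched open/close symbols per edge label and
a tag marker `*`; unordered subtrees are first canonicalized by recursively
sorting children (tagged child first).

The motivating application is branched biomolecules: a glycan's
monosaccharide connectivity is a rooted tree, and the nonterminals that a
minimum grammar reuses are exactly its repeated structural motifs.

## The method

For a budget *m*, a binary integer program decides whether a simple grammar
with *m* nonterminals exists:

* `x[s] = 1` iff a nonterminal generating span/subtree `s` appears;
* `y[d] = 1` iff bisection `d` is used (`2·y ≤ x_left + x_right`);
* `z[u] = 1` iff some nonterminal generates the substring / canonical Euler
  string `u` — nonterminals generating the same `u` are identified;

subject to: every single letter / single (possibly tagged) edge is generated;
every active non-base `x` is covered by at least one active division
(`x ≤ Σ y`); `z_u ≥ x_s` for every `s` in class `u`; and `Σ z ≤ m`.  The
program is feasible iff the root variable (whole string / whole tree) can
reach 1.  The minimum *m* is found either by one solve minimizing `Σ z` with
the root fixed (default) or by ascending feasibility probes; an explicit
grammar is then reconstructed from the solution, verified to regenerate the
input exactly, and serialized as JSON.  Solving is exact branch-and-bound
(HiGHS via `scipy.optimize.milp`), single-threaded and deterministic.

Tree candidates are the subtree indices `T[i, t, h, k]` (ordered: root `i`,
tag `t`, child span `h..k`) and `T[i, t, C]` (unordered: child subset `C`),
enumerated top-down from the whole tree so that only indices reachable in a
derivation become variables.

## Worked example

The 6-vertex tree whose edges `(1,2), (1,3), (1,6), (3,4), (3,5)` carry
labels `a, c, b, a, b` — a root with an `a`-edge, a `b`-edge, and a `c`-edge
whose lower endpoint again carries an `a`-edge and a `b`-edge:

```
$ treegram fixtures --name fig5 --out fig5.tsv
$ treegram tree --input fig5.tsv --mode unordered --min \
      --out fig5_grammar.json --patterns fig5_patterns.tsv
m=6 nonterminals=6 rhs_size=9 -> fig5_grammar.json
```

Treated as an *ordered* tree the minimum needs 7 nonterminals; as an
*unordered* tree it needs only 6, because the `{a-child, b-child}` subtree
hanging off the root and the one under the `c`-edge are unordered-isomorphic
and merge into a single nonterminal.  The six rules (keys are canonical
Euler strings; `*` marks the tag):

```
c * /c                   -> R1t  c        (tagged terminal c-edge)
a /a                     -> R1u  a
b /b                     -> R1u  b
a /a b /b                -> R2   a /a · b /b
c * /c a /a b /b         -> R2   a /a b /b · c * /c
a /a b /b c a /a b /b /c -> R3   (c * /c a /a b /b) ∘ (a /a b /b)
```

and the pattern report shows the reused 3-vertex motif:

```
pattern      occurrences  vertices  tagged  labels
a /a b /b    2            3         no      a,b
```

For strings: `treegram string --input abcabcab --min --out g.json` prints
`m=7` — seven nonterminals (three of them the letters `a, b, c`) suffice to
generate `abcabcab` and nothing else.  The `--method bisection` option runs
the TREE-BISECTION baseline instead of the IP; its grammars are never
smaller than the exact minimum.

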