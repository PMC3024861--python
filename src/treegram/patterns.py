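"""Repeated-subtree pattern extraction from a grammar's derivation.

A nonterminal expanded two or more times in the derivation tree marks a
subtree that occurs repeatedly in the input -- for glycans, a structural
motif.  Occurrences are counted in the derivation (how many times the
nonterminal is expanded), so they are non-overlapping by construction.
Tagged nonterminals (contexts with an attachment point) are reported too and
flagged as such, since cores of branched structures appear as tagged
contexts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .grammar import Grammar, GrammarError
from .tree import EPSILON, EulerString, tree_from_euler


@dataclass(frozen=True)
class Pattern:
    """One repeated subtree: its canonical Euler string, how often the
    derivation expands it, and its size."""

    key: str
    occurrences: int
    n_vertices: int
    n_edges: int
    labels: tuple[str, ...]
    tagged: bool
    rendering: str

    def __post_init__(self):
        if self.occurrences < 2:
            raise GrammarError("a pattern needs at least two occurrences")


def _render(es: EulerString) -> str:
    """Indented one-line-per-edge rendering of the subtree."""
    tree, tag = tree_from_euler(es)
    lines = ["."]

    def walk(v: int, depth: int) -> None:
        mark = " (tag)" if v == tag else ""
        lines.append("  " * depth + f"- {tree.label(v)}{mark}")
        if v != tag:
            for c in tree.ch(v):
                walk(c, depth + 1)

    for c in tree.ch(1):
        walk(c, 1)
    return "\n".join(lines)


def extract_repeats(g: Grammar) -> list[Pattern]:
    """All nonterminals expanded >= 2 times in the derivation, sorted by
    (occurrences, vertex count) descending."""
    if g.mode == "string":
        raise GrammarError("patterns are defined for tree grammars")
    if g.derivation is None:
        raise GrammarError("grammar carries no derivation")
    counts: Counter[str] = Counter()
    stack = [g.derivation]
    while stack:
        node = stack.pop()
        counts[node["key"]] += 1
        stack.extend(node.get("children", ()))
    out = []
    for key, c in counts.items():
        if c < 2:
            continue
        es = EulerString.from_text(key)
        out.append(
            Pattern(
                key=key,
                occurrences=c,
                n_vertices=es.n_vertices,
                n_edges=es.n_edges,
                labels=tuple(es.labels()),
                tagged=es.has_tag,
                rendering=_render(es),
            )
        )
    out.sort(key=lambda p: (-p.occurrences, -p.n_vertices, p.key))
    return out


def format_report(patterns: list[Pattern]) -> str:
    """Tabular text report, one row per pattern."""
    lines = ["pattern\toccurrences\tvertices\ttagged\tlabels"]
    for p in patterns:
        lines.append(
            f"{p.key}\t{p.occurrences}\t{p.n_vertices}\t"
            f"{'yes' if p.tagged else 'no'}\t{','.join(p.labels)}"
        )
    return "\n".join(lines) + "\n"
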