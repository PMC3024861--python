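"""File formats: tab-separated edge lists and KEGG KCF glycan records.

Edge-list format (one record per edge, optional header)::

    parent  child   label   rank

``rank`` orders siblings under their parent (ignored in unordered mode but
always written).  Vertex ids may be arbitrary; they are renumbered to 1-based
preorder on read, with the originals preserved in ``tree.original_ids``.

KCF (KEGG Chemical Function) records describe a glycan as NODE and EDGE
blocks.  The tree is rooted at the reducing-end monosaccharide (node 1 by
KCF convention) and each edge is labeled with a lower-case letter standing
for the sugar at its lower endpoint; letters are assigned deterministically
in first-seen (breadth-first) order and the sugar -> letter mapping is
returned alongside the tree so runs are reproducible.
"""

from __future__ import annotations

import string
from pathlib import Path

from .tree import EPSILON, LabeledTree, TreeError


class ParseError(TreeError):
    pass


# -- edge lists ------------------------------------------------------------

_HEADER = ("parent", "child", "label", "rank")


def read_edgelist(path) -> LabeledTree:
    """Read a tab-separated edge list into a :class:`LabeledTree`."""
    lines = Path(path).read_text().splitlines()
    records = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if ln == 1 and [p.lower() for p in parts[:2]] == ["parent", "child"]:
            continue
        if len(parts) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
        parent, child, label, rank = parts
        try:
            rank_i = int(rank)
        except ValueError:
            raise ParseError(f"{path}:{ln}: rank {rank!r} is not an integer")
        records.append((ln, parent, child, label, rank_i))
    if not records:
        raise ParseError(f"{path}: no edge records")
    seen_rank: dict[tuple, int] = {}
    for ln, parent, child, label, rank in records:
        if (parent, rank) in seen_rank:
            raise ParseError(
                f"{path}:{ln}: duplicate rank {rank} under parent {parent!r} "
                f"(first at line {seen_rank[(parent, rank)]})"
            )
        seen_rank[(parent, rank)] = ln
    records.sort(key=lambda r: (r[1], r[4]))
    try:
        return LabeledTree.from_edges([(p, c, lab) for _, p, c, lab, _ in records])
    except TreeError as e:
        raise ParseError(f"{path}: {e}") from e


def write_edgelist(tree: LabeledTree, path) -> None:
    lines = ["\t".join(_HEADER)]
    for p in sorted(tree.vertices()):
        for rank, c in enumerate(tree.ch(p), start=1):
            lines.append(f"{p}\t{c}\t{tree.label(c)}\t{rank}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- KCF -------------------------------------------------------------------

def _letters():
    for a in string.ascii_lowercase:
        yield a
    for a in string.ascii_lowercase:  # pragma: no cover - >26 sugars
        for b in string.ascii_lowercase:
            yield a + b


def read_kcf(path) -> tuple[LabeledTree, dict[str, str]]:
    """Parse one KCF record into a rooted tree plus the sugar->letter map."""
    nodes: dict[int, str] = {}
    links: list[tuple[int, int]] = []
    section = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if raw.startswith("///"):
            break
        stripped = raw.strip()
        if not stripped:
            continue
        head = raw.split()[0]
        if head in ("ENTRY", "NODE", "EDGE", "BRACKET"):
            section = head
            rest = raw.split()[1:]
            continue
        fields = stripped.split()
        if section == "NODE":
            try:
                nodes[int(fields[0])] = fields[1]
            except (IndexError, ValueError):
                raise ParseError(f"{path}:{ln}: malformed NODE line {raw!r}")
        elif section == "EDGE":
            try:
                a = int(fields[1].split(":")[0])
                b = int(fields[2].split(":")[0])
            except (IndexError, ValueError):
                raise ParseError(f"{path}:{ln}: malformed EDGE line {raw!r}")
            links.append((a, b))
    if not nodes:
        raise ParseError(f"{path}: missing NODE block")
    if not links:
        raise ParseError(f"{path}: no edges (single-residue glycans carry no tree)")
    root = 1 if 1 in nodes else min(nodes)
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for a, b in links:
        if a not in nodes or b not in nodes:
            raise ParseError(f"{path}: EDGE references unknown node ({a}, {b})")
        adj[a].append(b)
        adj[b].append(a)
    # orient away from the reducing end (root); letters in BFS first-seen order
    mapping: dict[str, str] = {}
    letters = _letters()
    edges: list[tuple[int, int, str]] = []
    seen = {root}
    frontier = [root]
    while frontier:
        v = frontier.pop(0)
        for w in sorted(adj[v]):
            if w in seen:
                continue
            seen.add(w)
            sugar = nodes[w]
            if sugar not in mapping:
                mapping[sugar] = next(letters)
            edges.append((v, w, mapping[sugar]))
            frontier.append(w)
    if len(seen) != len(nodes):
        raise ParseError(f"{path}: NODE/EDGE blocks are not a connected tree")
    if len(links) != len(nodes) - 1:
        raise ParseError(f"{path}: structure contains a cycle, not a tree")
    return LabeledTree.from_edges(edges), mapping
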