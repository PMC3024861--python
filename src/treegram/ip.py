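"""Integer programs for minimum simple grammars, and the minimum-m search.

Three instances are built over the candidates of :mod:`treegram.candidates`:

* strings (simple CFG, rules ``A -> a`` and ``A -> BC``),
* ordered trees (simple EOTG),
* unordered trees (simple EUTG).

All share one shape.  Binary variables:

* ``x[s]`` -- 1 iff a nonterminal generating span/subtree ``s`` appears,
* ``y[d]`` -- 1 iff division ``d`` is used (``y = 1`` implies both parts),
* ``z[u]`` -- 1 iff some nonterminal generates the substring / canonical
  Euler string ``u`` (nonterminals generating the same ``u`` are identified).

Constraints:

1. every base element (single letter; untagged leaf edge; optionally every
   tagged internal edge) is generated: ``x = 1``;
2. an active non-base ``x`` is covered by at least one division:
   ``x <= sum(y over divisions)``;
3. an active division implies both parts: ``2 y <= x_left + x_right``
   (one-directional linearization of the 'iff'; coverage pushes ``y`` up, so
   the optimum is preserved);
4. class activation: ``z[u] >= x[s]`` whenever ``s`` generates ``u``;
5. budget: ``sum(z) <= m`` (``<=`` keeps feasibility monotone in ``m``; any
   solution can be padded to equality; ``==`` is available as
   ``budget_mode="eq"``).

Feasibility mode maximizes the root variable; minimize mode fixes the root to
1 and minimizes ``sum(z)``, whose optimum is the minimum nonterminal count.

The solver backend is exact mixed-integer branch-and-bound (HiGHS through
``scipy.optimize.milp``): single-threaded and deterministic; a time limit is
reported as a distinct ``"timeout"`` status.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Literal, NamedTuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import candidates as cand
from .tree import (
    EPSILON,
    EulerString,
    LabeledTree,
    OrderedSubtree,
    UnorderedSubtree,
    canonicalize_unordered,
    euler_string,
)

Mode = Literal["cfg", "seotg", "seutg"]


class SolverError(RuntimeError):
    pass


@dataclass
class IPInstance:
    """A solver-agnostic binary program plus the bookkeeping needed to read a
    grammar back out of a solution."""

    kind: Mode
    objective: Literal["feasibility", "minimize"]
    m: int | None                      # budget; None in minimize mode
    budget_mode: Literal["le", "eq"]
    x: dict                            # span/subtree -> column
    y: dict                            # Division -> column
    z: dict[str, int]                  # class key (text) -> column
    key_of: dict                       # span/subtree -> class key (text)
    rows: list                         # (coeff dict, lb, ub)
    lb: np.ndarray
    root: object
    forced: list                       # base elements with x fixed to 1
    source: object                     # the input string or LabeledTree
    by_parent: dict = field(default_factory=dict)   # candidate -> divisions
    base_set: set = field(default_factory=set)      # all base candidates
    enum: object = None                # Enumeration (trees only)
    force_tagged_terminals: bool = True

    @property
    def n_vars(self) -> int:
        return len(self.x) + len(self.y) + len(self.z)

    def stats(self) -> dict:
        return {
            "x": len(self.x),
            "y": len(self.y),
            "z": len(self.z),
            "constraints": len(self.rows),
            "kind": self.kind,
        }


@dataclass
class SolveResult:
    status: Literal["optimal", "infeasible", "timeout", "error"]
    values: np.ndarray | None
    objective: float | None
    wall_time_s: float
    message: str = ""

    def value(self, instance: IPInstance, col: int) -> int:
        if self.values is None:
            raise SolverError(f"no assignment available (status={self.status})")
        return int(round(self.values[col]))

    def feasible_root(self, instance: IPInstance) -> bool:
        """In feasibility mode: did the root variable attain 1?"""
        if self.status != "optimal":
            return False
        return self.value(instance, instance.x[instance.root]) == 1

    def active_classes(self, instance: IPInstance) -> set[str]:
        return {
            u for u, col in instance.z.items() if self.value(instance, col) == 1
        }


class MinimumResult(NamedTuple):
    m: int
    instance: IPInstance
    result: SolveResult


# -- builders --------------------------------------------------------------

def _assemble(kind, objective, m, budget_mode, x_items, base, divisions,
              key_of, root, source, enum=None, force_tagged_terminals=True,
              is_tagged_base=None) -> IPInstance:
    if objective == "feasibility" and (m is None or m < 1):
        raise ValueError(f"budget m must be a positive integer, got {m!r}")
    x = {s: i for i, s in enumerate(x_items)}
    y = {d: len(x) + i for i, d in enumerate(divisions)}
    classes = sorted({key_of[s] for s in x_items})
    z = {u: len(x) + len(y) + i for i, u in enumerate(classes)}
    n = len(x) + len(y) + len(z)
    lb = np.zeros(n)

    forced = []
    for s in base:
        if is_tagged_base is not None and is_tagged_base(s):
            if not force_tagged_terminals:
                continue
        forced.append(s)
        lb[x[s]] = 1.0  # constraint (1)

    rows = []
    by_parent: dict = {}
    for d in divisions:
        by_parent.setdefault(d.parent, []).append(d)
    base_set = set(base)
    for s, col in x.items():
        if s in base_set:
            continue
        divs = by_parent.get(s, [])
        if not divs:
            raise cand.TreeError(f"non-base candidate {s!r} has no division")
        # (2) x <= sum y
        row = {y[d]: 1.0 for d in divs}
        row[col] = row.get(col, 0.0) - 1.0
        rows.append((row, 0.0, np.inf))
    for d, col in y.items():
        # (3) 2 y <= x_left + x_right
        row = {col: -2.0}
        for part in (d.left, d.right):
            pc = x[part]
            row[pc] = row.get(pc, 0.0) + 1.0
        rows.append((row, 0.0, np.inf))
    for s, col in x.items():
        # (4) z_u >= x_s
        zc = z[key_of[s]]
        rows.append(({zc: 1.0, col: -1.0}, 0.0, np.inf))
    if objective == "feasibility":
        # (5) sum z <= m (or == m)
        lo = float(m) if budget_mode == "eq" else 0.0
        rows.append(({c: 1.0 for c in z.values()}, lo, float(m)))
    else:
        lb[x[root]] = 1.0

    return IPInstance(
        kind=kind, objective=objective, m=m, budget_mode=budget_mode,
        x=x, y=y, z=z, key_of=key_of, rows=rows, lb=lb, root=root,
        forced=forced, source=source, by_parent=by_parent, base_set=base_set,
        enum=enum, force_tagged_terminals=force_tagged_terminals,
    )


def build_string_ip(
    s: str,
    m: int | None,
    budget_mode: str = "le",
    objective: str | None = None,
) -> IPInstance:
    """IP whose root variable ``x[1, n]`` attains 1 iff a simple CFG with at
    most ``m`` nonterminals generates exactly ``s``.

    With ``m=None`` the minimize variant is built instead (root fixed,
    objective ``sum z``).
    """
    if objective is None:
        objective = "feasibility" if m is not None else "minimize"
    spans = cand.enumerate_substrings(s)
    key_of = {(i, j): s[i - 1 : j] for (i, j) in spans}
    base = [(i, i) for i in range(1, len(s) + 1)]
    divisions = []
    for (i, j) in spans:
        if i == j:
            continue
        for k in range(i, j):
            divisions.append(
                cand.Division((i, j), "S", k, (i, k), (k + 1, j))
            )
    return _assemble(
        "cfg", objective, m, budget_mode, spans, base, divisions,
        key_of, (1, len(s)), s,
    )


def build_ordered_ip(
    tree: LabeledTree,
    m: int | None,
    budget_mode: str = "le",
    force_tagged_terminals: bool = True,
    objective: str | None = None,
) -> IPInstance:
    """IP for the minimum simple EOTG of an ordered tree (see module docs)."""
    if objective is None:
        objective = "feasibility" if m is not None else "minimize"
    enum = cand.enumerate_ordered(tree)
    key_of = {s: euler_string(tree, s).text for s in enum.subtrees}
    return _assemble(
        "seotg", objective, m, budget_mode, enum.subtrees, enum.base,
        enum.divisions, key_of, enum.root, tree, enum,
        force_tagged_terminals,
        is_tagged_base=lambda s: s.tag is not EPSILON,
    )


def build_unordered_ip(
    tree: LabeledTree,
    m: int | None,
    budget_mode: str = "le",
    force_tagged_terminals: bool = True,
    max_children: int = 16,
    objective: str | None = None,
) -> IPInstance:
    """IP for the minimum simple EUTG of an unordered tree.

    ``z`` classes are keyed by canonical Euler strings, so isomorphic
    unordered subtrees share one nonterminal.
    """
    if objective is None:
        objective = "feasibility" if m is not None else "minimize"
    enum = cand.enumerate_unordered(tree, max_children=max_children)
    key_of = {s: canonicalize_unordered(tree, s).text for s in enum.subtrees}
    return _assemble(
        "seutg", objective, m, budget_mode, enum.subtrees, enum.base,
        enum.divisions, key_of, enum.root, tree, enum,
        force_tagged_terminals,
        is_tagged_base=lambda s: s.tag is not EPSILON,
    )


# -- solving ---------------------------------------------------------------

def solve(
    instance: IPInstance,
    time_limit_s: float | None = None,
    seed: int | None = None,
    threads: int = 1,
) -> SolveResult:
    """Solve exactly with HiGHS branch-and-bound.

    Deterministic for a fixed instance (single-threaded exact search; the
    ``seed`` and ``threads`` knobs are part of the backend contract and are
    recorded, but HiGHS needs neither).  A hit time limit is reported as
    ``"timeout"``, never conflated with infeasibility.
    """
    n = instance.n_vars
    c = np.zeros(n)
    if instance.objective == "feasibility":
        c[instance.x[instance.root]] = -1.0
    else:
        for col in instance.z.values():
            c[col] = 1.0

    data, rows_ix, cols_ix, clb, cub = [], [], [], [], []
    for r, (row, lo, hi) in enumerate(instance.rows):
        for col, coef in row.items():
            rows_ix.append(r)
            cols_ix.append(col)
            data.append(coef)
        clb.append(lo)
        cub.append(hi)
    A = sparse.csr_matrix(
        (data, (rows_ix, cols_ix)), shape=(len(instance.rows), n)
    )
    constraints = LinearConstraint(A, np.array(clb), np.array(cub))
    options = {"presolve": True}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    t0 = time.perf_counter()
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(instance.lb, np.ones(n)),
        options=options,
    )
    wall = time.perf_counter() - t0
    status = {0: "optimal", 1: "timeout", 2: "infeasible"}.get(res.status, "error")
    if status == "optimal" and res.x is None:  # pragma: no cover - defensive
        status = "error"
    return SolveResult(
        status=status,
        values=None if res.x is None else np.asarray(res.x),
        objective=None if res.fun is None else float(res.fun),
        wall_time_s=wall,
        message=str(res.message),
    )


# -- minimum-m search ------------------------------------------------------

def _builder_for(source, mode: Mode, **kw) -> Callable[..., IPInstance]:
    if mode == "cfg":
        return lambda m, objective: build_string_ip(
            source, m, budget_mode=kw.get("budget_mode", "le"), objective=objective
        )
    if mode == "seotg":
        return lambda m, objective: build_ordered_ip(
            source, m,
            budget_mode=kw.get("budget_mode", "le"),
            force_tagged_terminals=kw.get("force_tagged_terminals", True),
            objective=objective,
        )
    if mode == "seutg":
        return lambda m, objective: build_unordered_ip(
            source, m,
            budget_mode=kw.get("budget_mode", "le"),
            force_tagged_terminals=kw.get("force_tagged_terminals", True),
            max_children=kw.get("max_children", 16),
            objective=objective,
        )
    raise ValueError(f"unknown mode {mode!r}")


def find_minimum_m(
    source: Union[str, LabeledTree],
    mode: Mode,
    strategy: Literal["minimize", "probe"] = "minimize",
    time_limit_s: float | None = None,
    seed: int | None = None,
    **kw,
) -> MinimumResult:
    """Smallest ``m`` for which the budgeted IP is feasible.

    ``strategy="minimize"`` (default): one solve of the minimize variant
    (root fixed to 1, objective ``sum z``).  ``strategy="probe"``: ascending
    feasibility probes starting at the forced-terminal-class lower bound;
    monotonicity of feasibility in ``m`` makes the two strategies agree.
    """
    build = _builder_for(source, mode, **kw)
    if strategy == "minimize":
        instance = build(None, "minimize")
        result = solve(instance, time_limit_s=time_limit_s, seed=seed)
        if result.status == "timeout":
            raise SolverError("minimize solve hit the time limit")
        if result.status != "optimal":
            raise SolverError(f"minimize solve failed: {result.status}")
        m = int(round(result.objective))
        return MinimumResult(m, instance, result)
    if strategy != "probe":
        raise ValueError(f"unknown strategy {strategy!r}")
    probe_instance = build(1, "feasibility")
    lower = len({probe_instance.key_of[s] for s in probe_instance.forced})
    upper = len(probe_instance.z)
    for m in range(max(lower, 1), upper + 1):
        instance = build(m, "feasibility")
        result = solve(instance, time_limit_s=time_limit_s, seed=seed)
        if result.status == "timeout":
            raise SolverError(f"feasibility probe at m={m} hit the time limit")
        if result.feasible_root(instance):
            return MinimumResult(m, instance, result)
    raise SolverError("no feasible budget up to the class count")  # pragma: no cover
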