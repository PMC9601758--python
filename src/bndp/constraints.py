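"""Edge and path prior constraints and the order-graph pruning rule.

Prior knowledge enters as four relation kinds: required/forbidden edges
(X must / must not be a direct parent of Y) and required/forbidden paths
(X must / must not be an ancestor of Y).  Required relations of either kind
imply an ancestral ordering, so they are pooled into one acyclic
*constraint graph*; its roots on the not-yet-placed variables decide which
variables may extend a subset during the dynamic program.  Forbidden
relations never prune the order graph — they restrict parent-set queries
only, because forbidding ancestry constrains structure, not placement
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .core import Dag, SubsetMask, iter_bits

Polarity = Literal["required", "forbidden"]


class ConstraintError(ValueError):
    """Raised when a constraint set is inconsistent or unsatisfiable."""


@dataclass(frozen=True)
class EdgeConstraint:
    parent: int
    child: int
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise ValueError("edge constraint endpoints must differ")


@dataclass(frozen=True)
class PathConstraint:
    """Ancestry constraint: ``ancestor`` is the head, ``descendant`` the tail."""

    ancestor: int
    descendant: int
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.ancestor == self.descendant:
            raise ValueError("path constraint endpoints must differ")


@dataclass
class ConstraintSet:
    """A collection of edge and path constraints over an ``n``-variable domain."""

    n: int
    edges: list[EdgeConstraint] = field(default_factory=list)
    paths: list[PathConstraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_e = set()
        for e in self.edges:
            if not (0 <= e.parent < self.n and 0 <= e.child < self.n):
                raise ValueError("edge constraint endpoint out of range")
            key = (e.parent, e.child, e.polarity)
            if key in seen_e:
                raise ValueError(f"duplicate edge constraint {key}")
            seen_e.add(key)
        seen_p = set()
        for p in self.paths:
            if not (0 <= p.ancestor < self.n and 0 <= p.descendant < self.n):
                raise ValueError("path constraint endpoint out of range")
            key = (p.ancestor, p.descendant, p.polarity)
            if key in seen_p:
                raise ValueError(f"duplicate path constraint {key}")
            seen_p.add(key)

    def __bool__(self) -> bool:
        return bool(self.edges or self.paths)

    # -- masks the queries and the DP consume ---------------------------------

    @property
    def var_set(self) -> SubsetMask:
        """Mask of every variable named by some constraint (vari(C))."""
        mask = 0
        for e in self.edges:
            mask |= (1 << e.parent) | (1 << e.child)
        for p in self.paths:
            mask |= (1 << p.ancestor) | (1 << p.descendant)
        return mask

    def required_parents(self, child: int) -> SubsetMask:
        mask = 0
        for e in self.edges:
            if e.polarity == "required" and e.child == child:
                mask |= 1 << e.parent
        return mask

    def forbidden_parents(self, child: int) -> SubsetMask:
        mask = 0
        for e in self.edges:
            if e.polarity == "forbidden" and e.child == child:
                mask |= 1 << e.parent
        return mask

    def required_ancestors(self, child: int) -> list[int]:
        return [
            p.ancestor
            for p in self.paths
            if p.polarity == "required" and p.descendant == child
        ]

    def forbidden_ancestors(self, child: int) -> list[int]:
        return [
            p.ancestor
            for p in self.paths
            if p.polarity == "forbidden" and p.descendant == child
        ]

    def required_path_tails(self) -> SubsetMask:
        """Mask of tail (descendant) endpoints of required path constraints."""
        mask = 0
        for p in self.paths:
            if p.polarity == "required":
                mask |= 1 << p.descendant
        return mask

    def required_relations(self) -> list[tuple[int, int]]:
        """(ancestor, descendant) pairs implied directly by required relations.

        A required edge implies ancestry, so edges and paths pool here.
        """
        rel = [
            (e.parent, e.child) for e in self.edges if e.polarity == "required"
        ]
        rel += [
            (p.ancestor, p.descendant)
            for p in self.paths
            if p.polarity == "required"
        ]
        return rel

    # -- JSON ------------------------------------------------------------------

    @classmethod
    def from_json(cls, doc: dict, names: Sequence[str]) -> "ConstraintSet":
        """Parse ``{"edges": [{"from","to","required"}], "paths": [...]}``.

        Variables are referenced by name; unknown names are hard errors.
        """
        index = {nm: i for i, nm in enumerate(names)}

        def resolve(nm: str) -> int:
            if nm not in index:
                raise ConstraintError(f"constraint references unknown variable {nm!r}")
            return index[nm]

        edges = [
            EdgeConstraint(
                resolve(e["from"]),
                resolve(e["to"]),
                "required" if e.get("required", True) else "forbidden",
            )
            for e in doc.get("edges", [])
        ]
        paths = [
            PathConstraint(
                resolve(p["from"]),
                resolve(p["to"]),
                "required" if p.get("required", True) else "forbidden",
            )
            for p in doc.get("paths", [])
        ]
        return cls(len(names), edges, paths)

    def to_json(self, names: Sequence[str]) -> dict:
        return {
            "edges": [
                {"from": names[e.parent], "to": names[e.child],
                 "required": e.polarity == "required"}
                for e in self.edges
            ],
            "paths": [
                {"from": names[p.ancestor], "to": names[p.descendant],
                 "required": p.polarity == "required"}
                for p in self.paths
            ],
        }


def load_constraints(path, names: Sequence[str]) -> ConstraintSet:
    with open(path, "r", encoding="utf-8") as fh:
        return ConstraintSet.from_json(json.load(fh), names)


# ---------------------------------------------------------------------------
# Consistency and the constraint graph
# ---------------------------------------------------------------------------

def _required_closure(c: ConstraintSet) -> set[tuple[int, int]]:
    """Transitive closure of the pooled required relation (Floyd-Warshall
    restricted to the constrained variables)."""
    rel = set(c.required_relations())
    nodes = sorted({v for pair in rel for v in pair})
    for k in nodes:
        for i in nodes:
            if (i, k) in rel:
                for j in nodes:
                    if (k, j) in rel:
                        rel.add((i, j))
    return rel


def check_consistency(c: ConstraintSet) -> list[str]:
    """Return a list of violation descriptions (empty means consistent).

    Detects (a) a pair declared both required and forbidden in the same
    relation, (b) cycles among required relations (mutual ancestry is
    impossible in a DAG), (c) a required edge whose reverse ancestry is
    required.
    """
    violations: list[str] = []
    edge_pol: dict[tuple[int, int], set[str]] = {}
    for e in c.edges:
        edge_pol.setdefault((e.parent, e.child), set()).add(e.polarity)
    for pair, pols in edge_pol.items():
        if len(pols) > 1:
            violations.append(f"edge {pair} is both required and forbidden")
    path_pol: dict[tuple[int, int], set[str]] = {}
    for p in c.paths:
        path_pol.setdefault((p.ancestor, p.descendant), set()).add(p.polarity)
    for pair, pols in path_pol.items():
        if len(pols) > 1:
            violations.append(f"path {pair} is both required and forbidden")

    closure = _required_closure(c)
    cyclic = sorted({a for (a, b) in closure if (b, a) in closure})
    if cyclic:
        violations.append(
            "required relations form a cycle among variables "
            + ", ".join(map(str, cyclic))
        )
    else:
        for e in c.edges:
            if e.polarity == "required" and (e.child, e.parent) in closure:
                violations.append(
                    f"required edge ({e.parent}, {e.child}) conflicts with a "
                    f"required reverse path"
                )
    return violations


@dataclass
class ConstraintGraph:
    """DAG over the constrained variables with one edge per required relation."""

    dag: Dag
    var_set: SubsetMask

    @property
    def n(self) -> int:
        return self.dag.n


def build_constraint_graph(c: ConstraintSet) -> ConstraintGraph:
    """Pool required edges and paths into the pruning DAG G_C.

    Raises :class:`ConstraintError` when the required relations are cyclic
    (the constraint set is then unsatisfiable).
    """
    parent_sets = [0] * c.n
    for a, d in set(c.required_relations()):
        parent_sets[d] |= 1 << a
    try:
        dag = Dag(c.n, parent_sets)
    except Exception as exc:
        raise ConstraintError(f"required constraints are unsatisfiable: {exc}") from exc
    return ConstraintGraph(dag, c.var_set)


def subgraph_roots(gc: ConstraintGraph, remaining: SubsetMask) -> SubsetMask:
    """Variables of ``remaining`` with no constraint-graph parent in ``remaining``."""
    roots = 0
    for v in iter_bits(remaining):
        if gc.dag.parent_sets[v] & remaining == 0:
            roots |= 1 << v
    return roots


def allowed_extensions(u: SubsetMask, gc: ConstraintGraph, n: int) -> SubsetMask:
    """Variables that may extend subset ``u`` in the order graph.

    Unconstrained variables are always admissible; of the constrained ones,
    only the roots of the constraint graph restricted to the not-yet-placed
    constrained variables may be appended (appending a non-root would place
    a descendant before a required ancestor).
    """
    full = (1 << n) - 1
    free = full & ~gc.var_set & ~u
    remaining = gc.var_set & ~u
    return free | subgraph_roots(gc, remaining)


def violates_order_constraint(u: SubsetMask, c: ConstraintSet) -> bool:
    """Subset-deletion predicate: some required ancestry X1 => X2 (taking the
    transitive closure of required relations) has X2 in ``u`` but X1 outside."""
    for a, d in _required_closure(c):
        if (u >> d) & 1 and not (u >> a) & 1:
            return True
    return False
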