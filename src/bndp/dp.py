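"""Layered order-graph dynamic programming with constraint pruning.

The order graph is the Hasse diagram of variable subsets: a subset U holds
the best score any network over exactly the variables of U can achieve, and
extending U by a sink X adds X's best admissible family score within U.
Required constraints prune subsets whose every completion would violate an
ancestry requirement (a pruned subset is never generated, by extending only
with constraint-graph roots); forbidden constraints act inside the
parent-set queries.

One :class:`OrderGraphEntry` is kept per admitted subset for the whole run
— enough to rebuild the best substructure ``g_u`` of any subset lazily
(path queries need its descendant sets) and to backtrace the final DAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .constraints import (
    ConstraintError,
    ConstraintGraph,
    ConstraintSet,
    allowed_extensions,
    build_constraint_graph,
    check_consistency,
)
from .core import Dag, SubsetMask, iter_bits, popcount, transitive_closure
from .parent_graph import (
    InfeasibleQueryError,
    SparseParentGraph,
    build_parent_graphs,
    query_best_parents,
)
from .scoring import LocalScoreTable, compute_score_cache

logger = logging.getLogger(__name__)


class NoSolutionError(RuntimeError):
    """The full variable set is unreachable under the given constraints."""


@dataclass(frozen=True)
class OrderGraphEntry:
    """Best route into one admitted subset of the order graph."""

    subset: SubsetMask
    score: float
    last_added: int
    best_parents_of_last: SubsetMask
    predecessor: SubsetMask


@dataclass
class DpResult:
    dag: Dag
    score: float
    entries: dict[SubsetMask, OrderGraphEntry] = field(repr=False, default_factory=dict)

    @property
    def planning_space(self) -> int:
        """Number of non-empty subsets the run actually admitted."""
        return len(self.entries) - 1


def _empty_constraints(n: int) -> ConstraintSet:
    return ConstraintSet(n)


def reconstruct_structure(
    final: SubsetMask, entries: dict[SubsetMask, OrderGraphEntry], n: int
) -> Dag:
    """Walk backpointers from ``final`` down to the empty set, assigning each
    variable the parent set recorded when it was appended."""
    parent_sets = [0] * n
    u = final
    while u:
        entry = entries.get(u)
        if entry is None:
            raise RuntimeError(f"broken backpointer chain at subset {u}")
        parent_sets[entry.last_added] = entry.best_parents_of_last
        u = entry.predecessor
    return Dag(n, parent_sets)


def dp_learn(
    spgs: Sequence[SparseParentGraph],
    c: ConstraintSet | None,
    n: int,
) -> DpResult:
    """Run the constrained dynamic program and return the optimal structure.

    ``spgs`` must have been built in the mode matching ``c`` (see
    :func:`bndp.parent_graph.build_parent_graphs`).
    """
    if c is None:
        c = _empty_constraints(n)
    violations = check_consistency(c)
    if violations:
        raise ConstraintError("; ".join(violations))
    gc = build_constraint_graph(c)

    # Which children ever need the substructure g_u at query time?
    needs_gu = [
        bool(c.required_ancestors(x) or c.forbidden_ancestors(x)) for x in range(n)
    ]

    entries: dict[SubsetMask, OrderGraphEntry] = {
        0: OrderGraphEntry(0, 0.0, -1, 0, -1)
    }
    substructure_cache: dict[SubsetMask, Dag] = {0: Dag(n)}

    def substructure(u: SubsetMask) -> Dag:
        g = substructure_cache.get(u)
        if g is None:
            g = reconstruct_structure(u, entries, n)
            substructure_cache[u] = g
        return g

    current = [0]
    full = (1 << n) - 1
    for layer in range(n):
        new_layer: dict[SubsetMask, OrderGraphEntry] = {}
        for u in current:
            base = entries[u].score
            ext = allowed_extensions(u, gc, n)
            for x in iter_bits(ext):
                g_u = substructure(u) if needs_gu[x] else None
                try:
                    pmask, pscore = query_best_parents(x, u, c, spgs[x], g_u)
                except InfeasibleQueryError:
                    continue
                new = u | (1 << x)
                cur = base + pscore
                inc = new_layer.get(new)
                if (
                    inc is None
                    or cur > inc.score
                    or (
                        cur == inc.score
                        and (x, pmask) < (inc.last_added, inc.best_parents_of_last)
                    )
                ):
                    new_layer[new] = OrderGraphEntry(new, cur, x, pmask, u)
        if not new_layer:
            raise NoSolutionError(
                f"order graph died at layer {layer + 1} of {n}: no admissible "
                f"extension satisfies the constraints"
            )
        entries.update(new_layer)
        current = list(new_layer)
        logger.info("layer %d: %d subsets admitted", layer + 1, len(new_layer))

    final_entry = entries[full]
    dag = reconstruct_structure(full, entries, n)
    return DpResult(dag, final_entry.score, entries)


# ---------------------------------------------------------------------------
# Planning-space accounting
# ---------------------------------------------------------------------------

def count_order_graph_entries(n: int, c: ConstraintSet | None = None) -> int:
    """Number of non-empty subsets the pruned order graph admits.

    Applies the subset-deletion predicate directly: a subset is pruned iff
    some required ancestry (in the closure of required relations) has its
    descendant inside and its ancestor outside.  With no required
    constraints this is ``2**n - 1``.
    """
    if c is None:
        c = _empty_constraints(n)
    violations = check_consistency(c)
    if violations:
        raise ConstraintError("; ".join(violations))
    gc = build_constraint_graph(c)
    anc = transitive_closure(gc.dag)
    tails = 0
    for d in range(n):
        if anc[d]:
            tails |= 1 << d
    if not tails:
        return (1 << n) - 1
    count = 0
    for u in range(1, 1 << n):
        ok = True
        for d in iter_bits(u & tails):
            if anc[d] & ~u:
                ok = False
                break
        if ok:
            count += 1
    return count


# ---------------------------------------------------------------------------
# High-level convenience
# ---------------------------------------------------------------------------

@dataclass
class LearnedNetwork:
    dag: Dag
    score: float
    names: list[str]
    nmp: int
    planning_space: int


def learn_network(
    data,
    c: ConstraintSet | None = None,
    nmp: int | None = None,
    cache: LocalScoreTable | None = None,
) -> LearnedNetwork:
    """Score the data, build parent graphs in the right mode, and run the DP."""
    if cache is None:
        cache = compute_score_cache(data, nmp)
    spgs = build_parent_graphs(cache, c)
    result = dp_learn(spgs, c, cache.n)
    return LearnedNetwork(
        result.dag, result.score, data.names, cache.nmp, result.planning_space
    )
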