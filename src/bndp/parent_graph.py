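"""Sparse parent graphs: pruned candidate parent sets and bitvector queries.

For each child the dynamic program repeatedly needs the best-scoring parent
set drawn from a candidate pool ``U`` (the subset already placed), subject
to the prior constraints.  The sparse parent graph stores the child's
candidate parent sets sorted by descending score, plus one *membership bit
array per variable* (bit ``t`` set iff stored set ``t`` contains the
variable).  A query then reduces to AND/OR operations over those bit
arrays followed by a first-set-bit lookup.

Three storage modes exist:

* ``unconstrained`` — dominance-pruned: a set is stored only when it
  strictly beats every stored proper subset.
* ``edge`` — as above, except sets containing a forbidden parent are never
  stored and dominance propagation never removes a required parent (so the
  chains a required-parent query walks remain intact).
* ``full`` — every parent set up to the parent bound, no dominance pruning;
  needed for tails of required path constraints, whose admissibility filter
  (must intersect an ancestor's descendant group) is not downward closed,
  so a dominated set can be the constrained optimum.

Bit arrays are plain Python integers indexed by stored-set position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .constraints import ConstraintSet
from .core import Dag, SubsetMask, iter_bits, popcount
from .scoring import LocalScoreTable

Mode = Literal["unconstrained", "edge", "full"]


class InfeasibleQueryError(LookupError):
    """No stored parent set satisfies the query constraints.

    A recoverable signal: the DP treats the offending leaf extension as
    invalid rather than aborting.
    """


@dataclass
class SparseParentGraph:
    """Per-child sorted candidate parent sets plus membership bit arrays."""

    child: int
    n: int
    parent_masks: list[SubsetMask]
    scores: list[float]
    membership: list[SubsetMask]
    mode: Mode

    @property
    def size(self) -> int:
        return len(self.parent_masks)

    @property
    def all_valid(self) -> SubsetMask:
        return (1 << self.size) - 1

    def rebuild_membership(self) -> list[SubsetMask]:
        """Recompute membership arrays from the stored masks (consistency check)."""
        return _membership(self.parent_masks, self.n)


def _membership(parent_masks: Sequence[SubsetMask], n: int) -> list[SubsetMask]:
    member = [0] * n
    for t, mask in enumerate(parent_masks):
        for v in iter_bits(mask):
            member[v] |= 1 << t
    return member


def _finish(
    child: int, n: int, entries: list[tuple[SubsetMask, float]], mode: Mode
) -> SparseParentGraph:
    # Descending score; ties broken toward the smaller mask so the "first
    # surviving set" of a query is deterministic across runs and platforms.
    entries.sort(key=lambda e: (-e[1], e[0]))
    masks = [m for m, _ in entries]
    scores = [s for _, s in entries]
    return SparseParentGraph(child, n, masks, scores, _membership(masks, n), mode)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _layered_masks(candidates: dict[SubsetMask, float]) -> list[SubsetMask]:
    """Candidate masks ordered by set size, so subsets precede supersets."""
    return sorted(candidates, key=popcount)


def build_spg_unconstrained(cache: LocalScoreTable, child: int) -> SparseParentGraph:
    """Dominance-pruned parent graph: store P iff score(P) strictly beats the
    best score among P's proper subsets."""
    candidates = cache.candidates(child)
    best: dict[SubsetMask, float] = {}
    stored: list[tuple[SubsetMask, float]] = []
    for mask in _layered_masks(candidates):
        s = candidates[mask]
        sub_best = float("-inf")
        for y in iter_bits(mask):
            sub_best = max(sub_best, best[mask & ~(1 << y)])
        if s > sub_best:
            best[mask] = s
            stored.append((mask, s))
        else:
            best[mask] = sub_best
    return _finish(child, cache.n, stored, "unconstrained")


def build_spg_edge(
    cache: LocalScoreTable, child: int, c: ConstraintSet
) -> SparseParentGraph:
    """Edge-constrained parent graph.

    Sets containing a forbidden parent of ``child`` are skipped outright
    (they, and all their supersets, can never be chosen), and the dominance
    comparison only drops non-required variables, so every stored chain
    retains the required parents.
    """
    required = c.required_parents(child)
    forbidden = c.forbidden_parents(child)
    candidates = cache.candidates(child)
    best: dict[SubsetMask, float] = {}
    stored: list[tuple[SubsetMask, float]] = []
    for mask in _layered_masks(candidates):
        if mask & forbidden:
            continue
        s = candidates[mask]
        sub_best = float("-inf")
        for y in iter_bits(mask & ~required):
            sub_best = max(sub_best, best[mask & ~(1 << y)])
        if s > sub_best:
            best[mask] = s
            stored.append((mask, s))
        else:
            best[mask] = sub_best
    return _finish(child, cache.n, stored, "edge")


def build_spg_path(
    cache: LocalScoreTable, child: int, c: ConstraintSet
) -> SparseParentGraph:
    """Path-constrained parent graph.

    Tails of required path constraints get the *full* table (all cached
    parent sets, no dominance pruning); any other child is built exactly as
    in the unconstrained case.  Forbidden-path filters are downward closed,
    so dominance pruning stays sound for them.
    """
    if (c.required_path_tails() >> child) & 1:
        entries = list(cache.candidates(child).items())
        return _finish(child, cache.n, entries, "full")
    return build_spg_unconstrained(cache, child)


def build_parent_graphs(
    cache: LocalScoreTable, c: ConstraintSet | None
) -> list[SparseParentGraph]:
    """Build one sparse parent graph per child in the mode its constraints need.

    Children that are tails of required path constraints get full storage;
    otherwise edge rules apply (which reduce to plain dominance pruning for
    children no edge constraint touches).
    """
    if c is None or not c:
        return [build_spg_unconstrained(cache, x) for x in range(cache.n)]
    tails = c.required_path_tails()
    spgs = []
    for x in range(cache.n):
        if (tails >> x) & 1:
            spgs.append(build_spg_path(cache, x, c))
        else:
            spgs.append(build_spg_edge(cache, x, c))
    return spgs


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _first_set_bit(valid: SubsetMask) -> int:
    return (valid & -valid).bit_length() - 1


def _containment_filter(spg: SparseParentGraph, u: SubsetMask) -> SubsetMask:
    """Bit array of stored sets that are subsets of ``u``."""
    valid = spg.all_valid
    outside = ((1 << spg.n) - 1) & ~u & ~(1 << spg.child)
    for y in iter_bits(outside):
        valid &= ~spg.membership[y]
    return valid


def query_best_parents_edge(
    child: int,
    u: SubsetMask,
    required: SubsetMask,
    forbidden: SubsetMask,
    spg: SparseParentGraph,
    return_valid: bool = False,
):
    """Best stored parent set within ``u`` containing all ``required`` and no
    ``forbidden`` variables.

    Implements the bitvector procedure: AND the membership row of every
    required variable, AND the complement row of every out-of-pool or
    forbidden variable, then take the first (highest-score) surviving set.
    """
    if required & ~u:
        raise ValueError("required parents must lie inside the candidate pool")
    if required & forbidden:
        raise ValueError("required and forbidden parents overlap")
    valid = _containment_filter(spg, u)
    for y in iter_bits(required & u):
        valid &= spg.membership[y]
    for y in iter_bits(forbidden & ~(1 << child)):
        valid &= ~spg.membership[y]
    valid &= spg.all_valid
    if not valid:
        raise InfeasibleQueryError(
            f"child {child}: no stored parent set satisfies the edge query"
        )
    idx = _first_set_bit(valid)
    result = (spg.parent_masks[idx], spg.scores[idx])
    return (*result, valid) if return_valid else result


def query_best_parents_path(
    child: int,
    u: SubsetMask,
    c: ConstraintSet,
    spg: SparseParentGraph,
    g_u: Dag,
    return_valid: bool = False,
):
    """Best stored parent set within ``u`` under path constraints.

    For each required ancestor X of ``child`` (all guaranteed to be inside
    ``u`` by order-graph pruning) the chosen set must intersect
    ``{X} ∪ descendants(X)`` evaluated in ``g_u``, the best substructure
    over ``u`` — realised as the OR of those membership rows (``Cvalid``)
    ANDed into ``valid``.  For each forbidden ancestor inside ``u`` the set
    must avoid that group entirely.
    """
    valid = _containment_filter(spg, u)
    closure = None
    required = c.required_ancestors(child)
    forbidden = c.forbidden_ancestors(child)
    if required or forbidden:
        from .core import descendant_masks

        des = descendant_masks(g_u)
        closure = des  # per-variable descendant masks within g_u
    for x in required:
        if not (u >> x) & 1:
            raise ValueError(
                f"required ancestor {x} of child {child} is outside the pool"
            )
        group = (closure[x] | (1 << x)) & u
        cvalid = 0
        for z in iter_bits(group):
            cvalid |= spg.membership[z]
        valid &= cvalid
    for x in forbidden:
        if not (u >> x) & 1:
            continue  # x will be placed after child; it can never be an ancestor
        group = (closure[x] | (1 << x)) & u
        for z in iter_bits(group):
            valid &= ~spg.membership[z]
    valid &= spg.all_valid
    if not valid:
        raise InfeasibleQueryError(
            f"child {child}: no stored parent set satisfies the path query"
        )
    idx = _first_set_bit(valid)
    result = (spg.parent_masks[idx], spg.scores[idx])
    return (*result, valid) if return_valid else result


def query_best_parents(
    child: int,
    u: SubsetMask,
    c: ConstraintSet | None,
    spg: SparseParentGraph,
    g_u: Dag | None = None,
) -> tuple[SubsetMask, float]:
    """General query applying whichever edge/path filters ``c`` declares.

    ``g_u`` is only consulted when path constraints touch ``child``.
    """
    if c is None or not c:
        valid = _containment_filter(spg, u) & spg.all_valid
        if not valid:
            raise InfeasibleQueryError(f"child {child}: empty candidate pool")
        idx = _first_set_bit(valid)
        return spg.parent_masks[idx], spg.scores[idx]

    valid = _containment_filter(spg, u)
    required = c.required_parents(child)
    if required & ~u:
        raise ValueError("required parents must lie inside the candidate pool")
    for y in iter_bits(required):
        valid &= spg.membership[y]
    for y in iter_bits(c.forbidden_parents(child)):
        valid &= ~spg.membership[y]

    req_anc = c.required_ancestors(child)
    forb_anc = [x for x in c.forbidden_ancestors(child) if (u >> x) & 1]
    if req_anc or forb_anc:
        if g_u is None:
            raise ValueError("path-constrained query needs the substructure g_u")
        from .core import descendant_masks

        des = descendant_masks(g_u)
        for x in req_anc:
            if not (u >> x) & 1:
                raise ValueError(
                    f"required ancestor {x} of child {child} is outside the pool"
                )
            cvalid = 0
            for z in iter_bits((des[x] | (1 << x)) & u):
                cvalid |= spg.membership[z]
            valid &= cvalid
        for x in forb_anc:
            for z in iter_bits((des[x] | (1 << x)) & u):
                valid &= ~spg.membership[z]

    valid &= spg.all_valid
    if not valid:
        raise InfeasibleQueryError(
            f"child {child}: no stored parent set satisfies the constraints"
        )
    idx = _first_set_bit(valid)
    return spg.parent_masks[idx], spg.scores[idx]
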