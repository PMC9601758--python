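"""Ground-truth generators, benchmark fixtures and the exhaustive oracle.

Provides seed-pinned random networks, forward (ancestral) sampling,
derivation of constraint sets from a known truth, the exhaustive-search
oracle used to certify the dynamic program on small domains, and the
embedded benchmark structures (Asia, Sachs, and an 18-node seeded random
stand-in for a "constructed" network).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product

import numpy as np

from .constraints import ConstraintSet, EdgeConstraint, PathConstraint
from .core import (
    BayesianNetwork,
    Dag,
    DiscreteDataset,
    SubsetMask,
    VariableSpec,
    is_acyclic,
    iter_bits,
    parent_config_index,
    structure_from_json,
    transitive_closure,
)
from .dp import NoSolutionError
from .scoring import LocalScoreTable


@dataclass(frozen=True)
class GeneratorConfig:
    """Random-network generator settings.

    ``edge_prob`` is the per-pair edge probability in the fixed topological
    order (variable index order); ``dirichlet_alpha`` the symmetric
    concentration for CPT rows.  Defaults describe a sparse binary network
    of the density typical for the discrete benchmarks emulated here
    (expected in-degree ~1.5 at n=6..18).
    """

    n: int
    edge_prob: float = 0.3
    cardinality: int = 2
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must lie in [0, 1]")
        if self.cardinality < 2:
            raise ValueError("cardinality must be >= 2")


def random_network(cfg: GeneratorConfig) -> BayesianNetwork:
    """Sample a DAG edge-wise in index (topological) order, then Dirichlet CPTs."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    parent_sets = [0] * n
    for j in range(n):
        for i in range(j):
            if rng.random() < cfg.edge_prob:
                parent_sets[j] |= 1 << i
    dag = Dag(n, parent_sets)
    specs = [VariableSpec(f"X{i + 1}", i, cfg.cardinality) for i in range(n)]
    cpts = []
    for i in range(n):
        q = cfg.cardinality ** dag.parent_sets[i].bit_count()
        cpts.append(
            rng.dirichlet([cfg.dirichlet_alpha] * cfg.cardinality, size=q)
        )
    return BayesianNetwork(dag, specs, cpts)


def forward_sample(bn: BayesianNetwork, N: int, seed: int = 0) -> DiscreteDataset:
    """Ancestral sampling: draw each variable given its sampled parents."""
    if N < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    cards = bn.cardinalities
    values = np.zeros((N, bn.n), dtype=np.int64)
    for v in bn.structure.topological_order():
        parents = list(iter_bits(bn.structure.parent_sets[v]))
        j = parent_config_index(values, parents, cards) if parents else np.zeros(N, dtype=np.int64)
        probs = bn.cpts[v][j]  # N x r
        u = rng.random(N)
        values[:, v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    return DiscreteDataset(values, list(bn.specs))


def sample_constraints_from_truth(
    truth: Dag, fraction: float, kind: str, seed: int = 0
) -> ConstraintSet:
    """Derive required constraints from a known structure.

    ``kind='edge'``: a uniformly random ``floor(fraction * |E|)``-subset of
    the true edges becomes required edge constraints.  ``kind='path'``: the
    same count of (ancestor, descendant) pairs drawn from the true
    transitive closure becomes required path constraints.  Both are
    consistent by construction (subrelations of an acyclic relation).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = truth.edges()
    count = math.floor(fraction * len(edges))
    if kind == "edge":
        chosen = rng.choice(len(edges), size=count, replace=False) if count else []
        return ConstraintSet(
            truth.n,
            edges=[EdgeConstraint(*edges[i], "required") for i in sorted(chosen)],
        )
    if kind == "path":
        anc = transitive_closure(truth)
        pairs = [(a, d) for d in range(truth.n) for a in iter_bits(anc[d])]
        count = min(count, len(pairs))
        chosen = rng.choice(len(pairs), size=count, replace=False) if count else []
        return ConstraintSet(
            truth.n,
            paths=[PathConstraint(*pairs[i], "required") for i in sorted(chosen)],
        )
    raise ValueError(f"unknown constraint kind {kind!r}")


# ---------------------------------------------------------------------------
# Exhaustive-search oracle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _acyclic_assignments(
    candidates: tuple[tuple[SubsetMask, ...], ...],
) -> list[tuple[tuple[SubsetMask, ...], tuple[SubsetMask, ...]]]:
    """All acyclic parent-mask assignments drawn from per-child candidates.

    Returns (parent_sets, ancestor_masks) tuples; cached because tests
    reuse the same candidate universe across many score tables.
    """
    n = len(candidates)
    out = []
    for assignment in product(*candidates):
        if is_acyclic(assignment, n):
            dag = Dag(n, list(assignment))
            out.append((assignment, tuple(transitive_closure(dag))))
    return out


def enumerate_dags(n: int, nmp: int | None = None) -> int:
    """Count the DAGs over ``n`` labelled nodes with in-degree <= ``nmp``."""
    if nmp is None:
        nmp = n - 1
    cands = tuple(
        tuple(
            m
            for m in range(1 << n)
            if not m & (1 << child) and m.bit_count() <= nmp
        )
        for child in range(n)
    )
    return len(_acyclic_assignments(cands))


def exhaustive_best_dag(
    cache: LocalScoreTable, c: ConstraintSet | None, n: int
) -> tuple[Dag, float]:
    """Brute-force optimum over every DAG buildable from the score cache.

    Enumerates all acyclic parent assignments (candidates are exactly the
    cached parent sets, i.e. the same search space the DP uses), discards
    those violating ``c`` — edges checked directly, paths via the
    transitive closure — and returns a maximum-score survivor.  Intended
    for ``n <= 5``.
    """
    if n > 6:
        raise ValueError("exhaustive enumeration is limited to n <= 6")
    cands = tuple(tuple(sorted(cache.candidates(x))) for x in range(n))
    req_e = fob_e = []
    req_p = fob_p = []
    if c is not None:
        req_e = [(e.parent, e.child) for e in c.edges if e.polarity == "required"]
        fob_e = [(e.parent, e.child) for e in c.edges if e.polarity == "forbidden"]
        req_p = [
            (p.ancestor, p.descendant) for p in c.paths if p.polarity == "required"
        ]
        fob_p = [
            (p.ancestor, p.descendant) for p in c.paths if p.polarity == "forbidden"
        ]

    best_score = float("-inf")
    best: tuple[SubsetMask, ...] | None = None
    scores = cache.scores
    for assignment, anc in _acyclic_assignments(cands):
        if any(not assignment[ch] & (1 << p) for p, ch in req_e):
            continue
        if any(assignment[ch] & (1 << p) for p, ch in fob_e):
            continue
        if any(not anc[d] & (1 << a) for a, d in req_p):
            continue
        if any(anc[d] & (1 << a) for a, d in fob_p):
            continue
        s = 0.0
        for child in range(n):
            s += scores[child][assignment[child]]
        if s > best_score or (s == best_score and best is not None and assignment < best):
            best_score = s
            best = assignment
    if best is None:
        raise NoSolutionError("no DAG in the search space satisfies the constraints")
    return Dag(n, list(best)), best_score


# ---------------------------------------------------------------------------
# Benchmark fixtures
# ---------------------------------------------------------------------------

#: §-style integer labels mapped to 0-based fixture variable order; each pair
#: (ancestor, descendant) holds in the true structure (verified in tests).
ASIA_PATH_PAIRS: list[tuple[int, int]] = [
    (0, 5), (1, 5), (1, 7), (2, 6), (2, 7), (3, 6), (3, 7)
]
SACHS_PATH_PAIRS: list[tuple[int, int]] = [
    (0, 1), (0, 3), (0, 4), (0, 6), (0, 7), (1, 4), (1, 7), (2, 3),
    (3, 5), (4, 5), (8, 10),
]

_SACHS_CPT_SEED = 7  # synthetic CPT stand-in, pinned
_CONSTRUCTED18_SEED = 73


def fixture_path_constraints(name: str) -> ConstraintSet:
    """The benchmark's required path constraints as a ConstraintSet."""
    bn = benchmark_fixture(name)
    pairs = {"asia": ASIA_PATH_PAIRS, "sachs": SACHS_PATH_PAIRS}.get(name)
    if pairs is None:
        raise ValueError(f"no path-constraint list for fixture {name!r}")
    return ConstraintSet(
        bn.n, paths=[PathConstraint(a, d, "required") for a, d in pairs]
    )


def _load_fixture_doc(stem: str) -> dict:
    ref = resources.files("bndp").joinpath(f"fixtures/{stem}.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def benchmark_fixture(name: str) -> BayesianNetwork:
    """Return an embedded benchmark network.

    ``asia``: the 8-node binary chest-clinic network with its canonical
    CPTs.  ``sachs``: the 11-node (3-state) protein-signalling consensus
    structure; its CPTs are a *synthetic* seed-pinned Dirichlet stand-in —
    the published parameterisation is not embedded, only the structure is
    authentic.  ``constructed18``: an 18-node seed-pinned random network
    standing in for an externally constructed benchmark.
    """
    if name == "asia":
        from .core import network_from_json

        return network_from_json(_load_fixture_doc("asia"))
    if name == "sachs":
        doc = _load_fixture_doc("sachs")
        dag, names = structure_from_json(doc)
        cards = [int(v["cardinality"]) for v in doc["variables"]]
        specs = [VariableSpec(nm, i, cards[i]) for i, nm in enumerate(names)]
        rng = np.random.default_rng(_SACHS_CPT_SEED)
        cpts = []
        for i in range(dag.n):
            q = 1
            for p in iter_bits(dag.parent_sets[i]):
                q *= cards[p]
            cpts.append(rng.dirichlet([1.0] * cards[i], size=q))
        return BayesianNetwork(dag, specs, cpts)
    if name == "constructed18":
        return random_network(
            GeneratorConfig(n=18, edge_prob=0.15, seed=_CONSTRUCTED18_SEED)
        )
    raise ValueError(f"unknown benchmark fixture {name!r}")
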