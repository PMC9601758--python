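"""Shared fixtures: random constraint draws and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import bndp as b
from bndp.core import iter_bits


def random_truth(n: int, rng: np.random.Generator, edge_prob: float = 0.4) -> b.Dag:
    """A random DAG drawn through the seeded generator."""
    cfg = b.GeneratorConfig(n=n, edge_prob=edge_prob, seed=int(rng.integers(2**31)))
    return b.random_network(cfg).structure


def random_consistent_constraints(
    n: int, rng: np.random.Generator, kind: str, k_required: int = 2, k_forbidden: int = 2
) -> b.ConstraintSet:
    """A consistent constraint set satisfiable by construction.

    Required relations are drawn from a hidden random DAG (edges or closure
    pairs); forbidden ones from its complement, so the hidden DAG witnesses
    satisfiability.
    """
    truth = random_truth(n, rng)
    edges = truth.edges()
    anc = b.transitive_closure(truth)
    closure_pairs = [(a, d) for d in range(n) for a in iter_bits(anc[d])]
    non_edges = [
        (i, j) for i in range(n) for j in range(n) if i != j and (i, j) not in edges
    ]
    non_closure = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and not (anc[j] >> i) & 1
    ]

    def pick(pool, k):
        k = min(k, len(pool))
        if not k:
            return []
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    if kind == "edge":
        es = [b.EdgeConstraint(p, c, "required") for p, c in pick(edges, k_required)]
        es += [
            b.EdgeConstraint(p, c, "forbidden") for p, c in pick(non_edges, k_forbidden)
        ]
        return b.ConstraintSet(n, edges=es)
    if kind == "path":
        ps = [
            b.PathConstraint(a, d, "required")
            for a, d in pick(closure_pairs, k_required)
        ]
        ps += [
            b.PathConstraint(a, d, "forbidden")
            for a, d in pick(non_closure, k_forbidden)
        ]
        return b.ConstraintSet(n, paths=ps)
    raise ValueError(kind)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_dataset(rng):
    """A 5-variable binary dataset of 200 rows from a random network."""
    bn = b.random_network(b.GeneratorConfig(n=5, seed=11))
    return b.forward_sample(bn, 200, seed=3)
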