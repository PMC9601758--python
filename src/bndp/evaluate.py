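"""Structural metrics, constraint verification and the experiment harness."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .constraints import ConstraintSet
from .core import Dag, transitive_closure
from .dp import count_order_graph_entries, learn_network
from .scoring import compute_score_cache, network_bic_score
from .simulate import benchmark_fixture, forward_sample, sample_constraints_from_truth


def shd(a: Dag, b: Dag) -> int:
    """Structural Hamming distance: insertions + deletions + reversals,
    with a reversal counting 1 (each unordered pair whose status differs
    contributes exactly one operation)."""
    if a.n != b.n:
        raise ValueError("DAGs must share a variable domain")

    def status(g: Dag, i: int, j: int) -> int:
        if g.parent_sets[j] & (1 << i):
            return 1  # i -> j
        if g.parent_sets[i] & (1 << j):
            return 2  # j -> i
        return 0

    dist = 0
    for i in range(a.n):
        for j in range(i + 1, a.n):
            if status(a, i, j) != status(b, i, j):
                dist += 1
    return dist


def edge_precision_recall(learned: Dag, truth: Dag) -> tuple[float, float]:
    """Directed-edge precision and recall of ``learned`` against ``truth``."""
    le, te = set(learned.edges()), set(truth.edges())
    tp = len(le & te)
    precision = tp / len(le) if le else 1.0
    recall = tp / len(te) if te else 1.0
    return precision, recall


def check_constraint_satisfaction(
    g: Dag, c: ConstraintSet
) -> tuple[bool, list[str]]:
    """Verify every constraint against the DAG (paths via transitive closure)."""
    violations: list[str] = []
    for e in c.edges:
        present = bool(g.parent_sets[e.child] & (1 << e.parent))
        if e.polarity == "required" and not present:
            violations.append(f"required edge {e.parent}->{e.child} missing")
        if e.polarity == "forbidden" and present:
            violations.append(f"forbidden edge {e.parent}->{e.child} present")
    anc = transitive_closure(g)
    for p in c.paths:
        present = bool(anc[p.descendant] & (1 << p.ancestor))
        if p.polarity == "required" and not present:
            violations.append(
                f"required path {p.ancestor}=>{p.descendant} missing"
            )
        if p.polarity == "forbidden" and present:
            violations.append(
                f"forbidden path {p.ancestor}=>{p.descendant} present"
            )
    return not violations, violations


@dataclass
class EvaluationReport:
    """Metrics of one constrained-vs-unconstrained learning run."""

    shd: int
    edge_precision: float
    edge_recall: float
    constraints_satisfied: bool
    score_learned: float
    score_unconstrained: float
    score_truth: float
    planning_space: int
    planning_space_unconstrained: int
    shd_unconstrained: int
    n_samples: int
    nmp: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


def run_experiment(
    fixture: str,
    n_samples: int,
    constraint_kind: str = "edge",
    fraction: float = 0.5,
    seed: int = 0,
    nmp: int | None = None,
    constraints: ConstraintSet | None = None,
) -> EvaluationReport:
    """Sample data from a benchmark truth, derive (or accept) constraints,
    learn with and without them, and report metrics for the constrained run.

    ``constraints`` overrides the truth-derived draw (used for the verbatim
    benchmark path lists).
    """
    truth_bn = benchmark_fixture(fixture)
    truth = truth_bn.structure
    data = forward_sample(truth_bn, n_samples, seed=seed)
    if constraints is None:
        constraints = sample_constraints_from_truth(
            truth, fraction, constraint_kind, seed=seed
        )

    cache = compute_score_cache(data, nmp)
    plain = learn_network(data, None, cache=cache)
    constrained = learn_network(data, constraints, cache=cache)

    satisfied, _ = check_constraint_satisfaction(constrained.dag, constraints)
    precision, recall = edge_precision_recall(constrained.dag, truth)
    return EvaluationReport(
        shd=shd(constrained.dag, truth),
        edge_precision=precision,
        edge_recall=recall,
        constraints_satisfied=satisfied,
        score_learned=constrained.score,
        score_unconstrained=plain.score,
        score_truth=network_bic_score(data, truth),
        planning_space=count_order_graph_entries(truth.n, constraints),
        planning_space_unconstrained=count_order_graph_entries(truth.n, None),
        shd_unconstrained=shd(plain.dag, truth),
        n_samples=n_samples,
        nmp=cache.nmp,
    )
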