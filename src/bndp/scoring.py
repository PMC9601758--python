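"""Decomposable BIC scoring of (child, parent-set) families from discrete data.

The score of a whole network is the sum over variables of the local family
score, so the dynamic program only ever consults a precomputed
:class:`LocalScoreTable`.  Natural logarithms are used throughout; the
penalty is ``(ln N / 2) * q * (r - 1)`` with ``q`` the full product of the
parent cardinalities (unobserved parent configurations still pay their
parameters) and ``r`` the child cardinality.

The parent bound ``nmp`` reflects that under BIC an optimal network's
in-degree is bounded once the penalty outweighs any attainable likelihood
gain; at small N this forces very sparse candidate families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import DiscreteDataset, Dag, SubsetMask, encode_subset, iter_bits


def max_parents(N: int, override: int | None = None) -> int:
    """Parent-count bound justified by the BIC penalty at sample size ``N``.

    Default formula ``ceil(log2(N / log2(N)))`` floored at 1; pass
    ``override`` to substitute a domain-specific bound.
    """
    if N < 2:
        raise ValueError("need at least 2 samples for a parent bound")
    if override is not None:
        if override < 0:
            raise ValueError("parent bound must be >= 0")
        return override
    bound = math.ceil(math.log2(N / math.log2(N)))
    return max(bound, 1)


def bic_local_score(data: DiscreteDataset, child: int, parents: SubsetMask) -> float:
    """BIC family score of ``child`` given the parent set ``parents``.

    Returns ``sum_jk N_jk ln(N_jk / N_j) - (ln N / 2) q (r - 1)`` with the
    convention ``0 ln 0 = 0``; ``j`` ranges over parent configurations and
    ``k`` over child states.
    """
    if parents & (1 << child):
        raise ValueError("child cannot be its own parent")
    N = data.n_samples
    cards = data.cardinalities
    r = cards[child]
    parent_idx = list(iter_bits(parents))
    q = 1
    for p in parent_idx:
        q *= cards[p]

    child_col = data.values[:, child]
    if parent_idx:
        from .core import parent_config_index

        j = parent_config_index(data.values, parent_idx, cards)
        joint = np.bincount(j * r + child_col, minlength=q * r).reshape(q, r)
    else:
        joint = np.bincount(child_col, minlength=r).reshape(1, r)

    nj = joint.sum(axis=1, keepdims=True)
    nz = joint > 0
    ll = float(np.sum(joint[nz] * np.log(joint[nz] / np.broadcast_to(nj, joint.shape)[nz])))
    penalty = 0.5 * math.log(N) * q * (r - 1)
    return ll - penalty


@dataclass
class LocalScoreTable:
    """Score cache: per child, a mapping parent mask -> family score."""

    n: int
    nmp: int
    scores: list[dict[SubsetMask, float]] = field(default_factory=list)

    def score(self, child: int, parents: SubsetMask) -> float:
        return self.scores[child][parents]

    def candidates(self, child: int) -> dict[SubsetMask, float]:
        return self.scores[child]

    def network_score(self, g: Dag) -> float:
        """Total score of a DAG as the sum of its cached family scores."""
        return sum(self.scores[c][g.parent_sets[c]] for c in range(self.n))

    # -- serialization (implementation-internal TSV) -------------------------

    def dump_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#n={self.n}\tnmp={self.nmp}\n")
            for child in range(self.n):
                for mask, s in sorted(self.scores[child].items()):
                    fh.write(f"{child}\t{mask}\t{s!r}\n")

    @classmethod
    def load_tsv(cls, path) -> "LocalScoreTable":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(kv.split("=") for kv in header.split("\t"))
            table = cls(int(meta["n"]), int(meta["nmp"]), [])
            table.scores = [dict() for _ in range(table.n)]
            for line in fh:
                child, mask, s = line.rstrip("\n").split("\t")
                table.scores[int(child)][int(mask)] = float(s)
        return table


def compute_score_cache(
    data: DiscreteDataset, nmp: int | None = None
) -> LocalScoreTable:
    """Score every (child, parent set) family with ``|parents| <= nmp``.

    ``nmp`` defaults to :func:`max_parents` at the dataset's sample size and
    is always capped at ``n - 1``.
    """
    n = data.n_variables
    if nmp is None:
        nmp = max_parents(data.n_samples)
    if nmp < 0:
        raise ValueError("nmp must be >= 0")
    nmp = min(nmp, n - 1)
    table = LocalScoreTable(n, nmp, [dict() for _ in range(n)])
    for child in range(n):
        others = [v for v in range(n) if v != child]
        for size in range(nmp + 1):
            for combo in combinations(others, size):
                mask = encode_subset(combo, n)
                table.scores[child][mask] = bic_local_score(data, child, mask)
    return table


def network_bic_score(data: DiscreteDataset, g: Dag) -> float:
    """Whole-network BIC computed directly (no cache, no parent bound)."""
    return sum(bic_local_score(data, c, g.parent_sets[c]) for c in range(g.n))


def random_score_table(
    n: int, nmp: int, rng: np.random.Generator, scale: float = 1.0
) -> LocalScoreTable:
    """A synthetic score table (i.i.d. normal scores) for oracle testing.

    Not a data score — used to exercise the DP/query machinery over
    arbitrary decomposable score landscapes.
    """
    nmp = min(nmp, n - 1)
    table = LocalScoreTable(n, nmp, [dict() for _ in range(n)])
    for child in range(n):
        others = [v for v in range(n) if v != child]
        for size in range(nmp + 1):
            for combo in combinations(others, size):
                mask = encode_subset(combo, n)
                table.scores[child][mask] = float(rng.normal(scale=scale))
    return table
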