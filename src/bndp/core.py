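"""Domain types for discrete Bayesian networks and the subset-mask encoding.

Every other module indexes its tables by :class:`SubsetMask` values — plain
Python integers in which bit ``i`` is set iff the variable with index ``i``
belongs to the subset.  Because Python integers are arbitrary precision the
domain size is not capped at a machine word, though memory bounds practical
use at roughly ``n <= 24`` (tables hold one entry per subset).

Variable indexing is 0-based throughout; all file formats reference
variables by name, never by raw index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

#: A variable subset encoded as an integer bit mask (type alias).
SubsetMask = int


class StructureError(ValueError):
    """Raised when a graph violates a structural invariant (e.g. a cycle)."""


# ---------------------------------------------------------------------------
# Subset masks
# ---------------------------------------------------------------------------

def encode_subset(members: Iterable[int], n: int) -> SubsetMask:
    """Encode variable indices as a bit mask over a domain of size ``n``.

    Bit ``i`` of the result is 1 iff variable ``i`` is a member.  The map is
    a bijection between subsets of ``{0, ..., n-1}`` and integers in
    ``[0, 2**n)``.
    """
    mask = 0
    for i in members:
        if not 0 <= i < n:
            raise ValueError(f"variable index {i} out of range for n={n}")
        mask |= 1 << i
    return mask


def decode_subset(mask: SubsetMask) -> list[int]:
    """Return the sorted variable indices present in ``mask``."""
    if mask < 0:
        raise ValueError("subset mask must be non-negative")
    return list(iter_bits(mask))


def iter_bits(mask: SubsetMask) -> Iterator[int]:
    """Yield the set bit positions of ``mask`` in increasing order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def popcount(mask: SubsetMask) -> int:
    return mask.bit_count()


# ---------------------------------------------------------------------------
# Variables and datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """A discrete variable: display name, global index, number of states."""

    name: str
    index: int
    cardinality: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.cardinality < 2:
            raise ValueError(f"{self.name}: cardinality must be >= 2")
        if self.index < 0:
            raise ValueError(f"{self.name}: index must be >= 0")


def validate_specs(specs: Sequence[VariableSpec]) -> None:
    """Check that indices are contiguous 0..n-1 and names unique."""
    n = len(specs)
    if sorted(s.index for s in specs) != list(range(n)):
        raise ValueError("variable indices must be unique and contiguous 0..n-1")
    names = {s.name for s in specs}
    if len(names) != n:
        raise ValueError("variable names must be unique")


@dataclass
class DiscreteDataset:
    """An N x n table of integer state codes plus the variable specs."""

    values: np.ndarray
    specs: list[VariableSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.values.shape[1] != len(self.specs):
            raise ValueError("column count does not match variable specs")
        validate_specs(self.specs)
        for s in sorted(self.specs, key=lambda s: s.index):
            col = self.values[:, s.index]
            if col.min() < 0 or col.max() >= s.cardinality:
                raise ValueError(
                    f"column {s.name!r} contains codes outside [0, {s.cardinality})"
                )

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_variables(self) -> int:
        return int(self.values.shape[1])

    @property
    def names(self) -> list[str]:
        return [s.name for s in sorted(self.specs, key=lambda s: s.index)]

    @property
    def cardinalities(self) -> list[int]:
        return [s.cardinality for s in sorted(self.specs, key=lambda s: s.index)]

    # -- I/O ----------------------------------------------------------------

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.names)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, cardinalities: dict[str, int] | None = None) -> "DiscreteDataset":
        """Load a dataset from CSV (header of names, integer state codes).

        Cardinalities default to ``max(column) + 1``; pass a mapping to
        declare states never observed in the sample.
        """
        import pandas as pd

        df = pd.read_csv(path)
        specs = []
        for i, name in enumerate(df.columns):
            card = (cardinalities or {}).get(name, int(df[name].max()) + 1)
            specs.append(VariableSpec(str(name), i, max(card, 2)))
        return cls(df.to_numpy(dtype=np.int64), specs)


# ---------------------------------------------------------------------------
# DAGs
# ---------------------------------------------------------------------------

@dataclass
class Dag:
    """A directed acyclic graph stored as one parent mask per variable."""

    n: int
    parent_sets: list[SubsetMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parent_sets:
            self.parent_sets = [0] * self.n
        if len(self.parent_sets) != self.n:
            raise ValueError("parent_sets length must equal n")
        for i, mask in enumerate(self.parent_sets):
            if mask >> self.n:
                raise ValueError(f"parent mask of variable {i} exceeds domain")
            if mask & (1 << i):
                raise StructureError(f"variable {i} cannot be its own parent")
        if not is_acyclic(self.parent_sets, self.n):
            raise StructureError("parent sets contain a directed cycle")

    # -- derived views -------------------------------------------------------

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) index pairs, sorted."""
        return [
            (p, c) for c in range(self.n) for p in iter_bits(self.parent_sets[c])
        ]

    def children_mask(self, v: int) -> SubsetMask:
        mask = 0
        for c in range(self.n):
            if self.parent_sets[c] & (1 << v):
                mask |= 1 << c
        return mask

    def roots(self) -> SubsetMask:
        """Variables with no parents."""
        return encode_subset(
            [i for i in range(self.n) if not self.parent_sets[i]], self.n
        )

    def leaves(self) -> SubsetMask:
        """Variables that appear in no parent set."""
        used = 0
        for mask in self.parent_sets:
            used |= mask
        return ((1 << self.n) - 1) & ~used

    def topological_order(self) -> list[int]:
        order = _topological_order(self.parent_sets, self.n)
        if order is None:  # pragma: no cover - guarded by __post_init__
            raise StructureError("graph has a directed cycle")
        return order

    def ancestors(self, v: int) -> SubsetMask:
        return transitive_closure(self)[v]

    def descendants(self, v: int) -> SubsetMask:
        closure = transitive_closure(self)
        mask = 0
        for y in range(self.n):
            if closure[y] & (1 << v):
                mask |= 1 << y
        return mask

    # -- export --------------------------------------------------------------

    def to_dot(self, names: Sequence[str] | None = None) -> str:
        names = list(names) if names else [f"X{i + 1}" for i in range(self.n)]
        lines = ["digraph G {"]
        for i in range(self.n):
            lines.append(f'  "{names[i]}";')
        for p, c in self.edges():
            lines.append(f'  "{names[p]}" -> "{names[c]}";')
        lines.append("}")
        return "\n".join(lines)

    def to_edge_tsv(self, names: Sequence[str] | None = None) -> str:
        names = list(names) if names else [f"X{i + 1}" for i in range(self.n)]
        return "".join(f"{names[p]}\t{names[c]}\n" for p, c in self.edges())


def _topological_order(parent_sets: Sequence[SubsetMask], n: int) -> list[int] | None:
    """Kahn's algorithm on parent masks; None when a cycle blocks it."""
    remaining = list(parent_sets)
    placed = 0
    order: list[int] = []
    while len(order) < n:
        progressed = False
        for v in range(n):
            if placed & (1 << v):
                continue
            if remaining[v] & ~placed == 0:
                order.append(v)
                placed |= 1 << v
                progressed = True
        if not progressed:
            return None
    return order


def is_acyclic(parent_sets: Sequence[SubsetMask], n: int) -> bool:
    """True iff a topological order exists for the given parent masks."""
    return _topological_order(parent_sets, n) is not None


def transitive_closure(g: Dag) -> list[SubsetMask]:
    """Per-variable ancestor masks: bit X of entry Y is set iff X => Y.

    Computed by propagating ancestor masks along a topological order, so a
    cyclic input raises :class:`StructureError` (via ``topological_order``).
    """
    anc = [0] * g.n
    for v in g.topological_order():
        mask = g.parent_sets[v]
        for p in iter_bits(g.parent_sets[v]):
            mask |= anc[p]
        anc[v] = mask
    return anc


def descendant_masks(g: Dag) -> list[SubsetMask]:
    """Transpose view of :func:`transitive_closure` (per-variable descendants)."""
    anc = transitive_closure(g)
    des = [0] * g.n
    for y in range(g.n):
        for x in iter_bits(anc[y]):
            des[x] |= 1 << y
    return des


# ---------------------------------------------------------------------------
# Bayesian networks (structure + CPTs)
# ---------------------------------------------------------------------------

def parent_config_index(
    rows: np.ndarray, parents: Sequence[int], cardinalities: Sequence[int]
) -> np.ndarray:
    """Mixed-radix index of each row's parent configuration.

    The most significant digit is the lowest parent index — the one fixed
    convention used by CPT fixtures, scoring and sampling alike.
    """
    idx = np.zeros(rows.shape[0], dtype=np.int64)
    for p in sorted(parents):
        idx = idx * cardinalities[p] + rows[:, p]
    return idx


@dataclass
class BayesianNetwork:
    """A DAG plus one conditional probability table per variable.

    ``cpts[i]`` has shape ``(q_i, r_i)`` where ``q_i`` is the product of the
    parents' cardinalities (1 for roots) and ``r_i`` the variable's own
    cardinality; each row is a distribution over the child's states.
    """

    structure: Dag
    specs: list[VariableSpec]
    cpts: list[np.ndarray]

    def __post_init__(self) -> None:
        validate_specs(self.specs)
        if len(self.specs) != self.structure.n or len(self.cpts) != self.structure.n:
            raise ValueError("specs/cpts length must match the structure")
        cards = self.cardinalities
        for i in range(self.structure.n):
            q = 1
            for p in iter_bits(self.structure.parent_sets[i]):
                q *= cards[p]
            cpt = np.asarray(self.cpts[i], dtype=float)
            if cpt.shape != (q, cards[i]):
                raise ValueError(
                    f"CPT of {self.specs[i].name!r} has shape {cpt.shape}, "
                    f"expected {(q, cards[i])}"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {self.specs[i].name!r} must sum to 1")
            self.cpts[i] = cpt

    @property
    def n(self) -> int:
        return self.structure.n

    @property
    def names(self) -> list[str]:
        return [s.name for s in sorted(self.specs, key=lambda s: s.index)]

    @property
    def cardinalities(self) -> list[int]:
        return [s.cardinality for s in sorted(self.specs, key=lambda s: s.index)]


# ---------------------------------------------------------------------------
# Network fixture JSON
# ---------------------------------------------------------------------------

def network_to_json(bn: BayesianNetwork) -> dict:
    """Serialize structure + CPTs to the fixture dict format."""
    names = bn.names
    return {
        "variables": [
            {"name": s.name, "cardinality": s.cardinality}
            for s in sorted(bn.specs, key=lambda s: s.index)
        ],
        "edges": [[names[p], names[c]] for p, c in bn.structure.edges()],
        "cpts": {names[i]: bn.cpts[i].tolist() for i in range(bn.n)},
    }


def dag_to_json(g: Dag, names: Sequence[str]) -> dict:
    return {
        "variables": [{"name": nm} for nm in names],
        "edges": [[names[p], names[c]] for p, c in g.edges()],
    }


def structure_from_json(doc: dict) -> tuple[Dag, list[str]]:
    """Read a DAG (names + edges) from the fixture dict format."""
    names = [v["name"] for v in doc["variables"]]
    index = {nm: i for i, nm in enumerate(names)}
    if len(index) != len(names):
        raise ValueError("duplicate variable names in network document")
    n = len(names)
    parent_sets = [0] * n
    for parent, child in doc["edges"]:
        if parent not in index or child not in index:
            raise ValueError(f"edge references unknown variable: {parent}->{child}")
        parent_sets[index[child]] |= 1 << index[parent]
    return Dag(n, parent_sets), names


def network_from_json(doc: dict) -> BayesianNetwork:
    """Read a full network (structure + CPTs) from the fixture dict format."""
    dag, names = structure_from_json(doc)
    specs = [
        VariableSpec(v["name"], i, int(v["cardinality"]))
        for i, v in enumerate(doc["variables"])
    ]
    cpts = [np.asarray(doc["cpts"][nm], dtype=float) for nm in names]
    return BayesianNetwork(dag, specs, cpts)


def load_network(path) -> BayesianNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return network_from_json(json.load(fh))


def save_network(bn: BayesianNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(network_to_json(bn), fh, indent=1)
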