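# Methods

## Model and scoring

A Bayesian network over discrete variables X₁…Xₙ is a DAG G plus one
conditional probability table per variable. Structure learning maximises
the BIC, natural-log throughout:

    Score(X, Pa(X)) = Σ_{j,k} N_jk ln(N_jk / N_j) − (ln N / 2) · q · (r − 1)

with j over parent configurations, k over child states, q the product of
the parents' cardinalities, r the child's cardinality, and 0·ln 0 ≡ 0.
Unobserved parent configurations contribute nothing to the likelihood but
q still counts them in the penalty — the standard BIC convention, and the
deterministic choice. The network score is the sum of family scores
(decomposability), which is what makes the subset dynamic program exact.

Candidate parent sets are capped at `nmp` parents per child, default
⌈log₂(N / log₂ N)⌉ floored at 1 (N = sample size; at N = 20 this is 3, at
N = 1000 it is 7), always additionally capped at n − 1 and overridable
(`--max-parents`). The cap reflects that under BIC an optimal network's
in-degree cannot grow faster than the penalty allows; the specific ceiling
form is one reading of the ambiguous bound usually quoted for it, chosen
because it is tunable and reproduces the intended "few parents at small N"
behaviour.

## The dynamic program

`maxScore(U)` over subsets U obeys the sink recurrence: the best network on
U is the best network on U\{X} plus X attached as a sink with its best
parent set inside U\{X}. The DP sweeps subsets in layers of increasing
cardinality, keeping one entry per subset: best score, the variable added
last, its chosen parents, and a backpointer. The final full-set entry
backtraces to the optimal DAG (acyclic by construction: parents always
precede their child in the induced order).

One deliberate deviation from a strict two-layer frontier: all per-subset
entries are retained for the whole run in a single hash map. Path queries
need the best substructure g_U of arbitrary earlier subsets (reconstructed
lazily, memoized), and at the package's practical scales (n ≤ ~20) the map
is the same one-entry-per-subset space the planning-space accounting
already implies, so a spill/eviction scheme would add complexity without
changing the asymptotics.

Planning-space accounting (`count_order_graph_entries`) counts the
non-empty admitted subsets — 2ⁿ − 1 when nothing is required (262,143 at
n = 18) — by applying the deletion predicate below to every subset.

## Constraints

Relations: required/forbidden edges (direct parenthood) and paths
(ancestry). Consistency checking flags pairs declared both required and
forbidden, cycles among required relations, and a required edge whose
reverse ancestry is required. A required edge implies ancestry, so required
edges and paths pool into one acyclic **constraint graph** G_C.

**Pruning rule.** A subset U is inadmissible iff some required ancestry
X ⇒ Y (in the transitive closure of required relations) has Y ∈ U but
X ∉ U — once Y is placed without X, every completion orders X after Y.
Rather than test every subset, the DP only extends U by variables that are
either unconstrained or roots of G_C restricted to the not-yet-placed
constrained variables; the test suite verifies (for n ≤ 6, random
constraint sets) that the subsets so generated are exactly those passing
the predicate. "Inferred from C" is implemented as reachability in the
required-relation graph — the only inference rule the machinery supports.
Forbidden relations never prune: they constrain structure, not placement
order, and act purely inside queries.

**Sparse parent graphs.** Per child, candidate sets are stored sorted by
descending score (ties to the smaller set mask, fixed at sort time, so
every query is deterministic across platforms), alongside per-variable
membership bit arrays over stored-set positions. Three modes:

* unconstrained: dominance-pruned — a set is stored only if it strictly
  beats every proper subset's best;
* edge mode: sets containing a forbidden parent are skipped outright, and
  dominance propagation never drops a required parent, so the chains a
  required-parent query relies on stay intact;
* full mode: every cached set, no pruning — used for tails of *required*
  path constraints, whose admissibility filter ("intersect the ancestor's
  descendant group") is not downward closed, so a dominated set can be the
  constrained optimum. Forbidden-path filters *are* downward closed
  (a superset of an intersecting set also intersects), so dominance
  pruning stays sound for them and non-tail children keep the pruned
  table.

"Below nmp" is read inclusively and the empty set is always a candidate
(otherwise root nodes would be impossible).

**Queries.** Start from an all-ones validity bit array; AND out sets
containing out-of-pool variables; AND membership rows of required parents;
AND complement rows of forbidden parents; for each required ancestor X of
the child, OR the membership rows of {X} ∪ descendants(X in g_U) into an
auxiliary array and AND it in (initialised to all zeros — the worked
example's arithmetic requires OR-accumulation from zero); for each
forbidden ancestor inside U, AND out that whole group (an ancestor not yet
placed can never become one: the child's parents are fixed inside U and
all ancestral chains into U stay inside U). The first surviving position is
the answer. An empty survivor set raises a recoverable infeasibility
signal: the DP simply skips that extension, and if a whole layer dies the
run reports which layer was over-constrained.

## Known optimality gap under path constraints

Required-ancestor filters are evaluated against the *single stored best*
substructure g_U. A lower-scoring substructure over the same subset can
expose different descendant sets that enable a much better tail family, so
the procedure is exact under edge constraints and no constraints but mildly
greedy under required path constraints. Measured against the exhaustive
constrained optimum on random score tables (n = 3..5, 50 tables per size,
mixed required/forbidden draws): identical scores in ~94% of
path-constrained instances, strictly lower in the rest, never higher, and
the returned structure always satisfies every constraint. The
oracle-equivalence test logs each counterexample; the path leg of that
test fails by design until the procedure itself is changed (e.g. keeping
multiple substructures per subset), which is out of scope.

## Synthetic data and fixtures

`random_network` draws a DAG edge-wise in index order (per-pair probability
`edge_prob`, default 0.3 — a sparse expected in-degree around 1–1.5 at
n = 6..18, typical of the discrete benchmarks emulated) with symmetric
Dirichlet CPT rows (`dirichlet_alpha`, default 1.0, i.e. uniform over the
simplex); `forward_sample` draws rows ancestrally. Identical seeds
reproduce networks and samples bit-exactly.

What the generator does **not** emulate: real benchmark CPTs' determinism
and extreme marginals, missing data, and selection effects; a green
recovery test therefore establishes consistency of the scoring + search
machinery, not field performance. The structure-recovery target (6-node
nets, N = 5000, 20 replicates, median SHD ≤ 2) passes with the defaults;
the residual distance is mostly within-equivalence-class edge reversals,
which BIC cannot orient.

Fixtures: `asia` embeds the canonical 8-node network with its published
CPTs; `sachs` embeds the 11-node consensus *structure* with seed-pinned
synthetic Dirichlet CPTs (the real parameterisation is not redistributed
here; every property tested — constraint satisfaction, score dominance,
space reduction — is CPT-agnostic); `constructed18` is a seed-pinned
generator draw standing in for an externally constructed 18-node network,
so its exact topology is not meaningful, only its statistical class. The
benchmark ancestor-pair prior lists (`ASIA_PATH_PAIRS`, `SACHS_PATH_PAIRS`)
use a label-to-variable mapping chosen as the unique causal-layer ordering
under which every listed pair is true in the embedded structure; tests
verify this. The path-query worked example's substructure (X1→X3, X2→X4,
X4→X3) is the minimal graph consistent with the example's published
auxiliary bit rows; the ambiguity (whether X3 descends from X2 directly or
via X4) does not affect any queried quantity.

## Numerical and degenerate-input choices

* Scores are finite log-scale floats; infeasibility is a signal, never a
  sentinel score.
* DP route ties at equal score keep the smaller (last-added variable,
  parent mask) pair; query ties keep the smaller mask — all outputs are
  deterministic functions of (data, constraints, seed).
* A dataset column never observed in some state still declares its full
  cardinality through `VariableSpec` (CSV ingestion defaults to
  max(code)+1, with an override mapping).
* n = 1 learns the empty DAG; nmp = 0 forces it; an empty dataset and
  N < 2 are rejected up front.
* `exhaustive_best_dag` (the test oracle) enumerates every acyclic parent
  assignment drawn from the same score cache the DP uses — same search
  space, independent mechanism — and is bounded to n ≤ 6.

## Limitations

Exponential in n by design (subset tables); practical to n ≈ 20. No
missing data, no latent or continuous variables, no BDeu/K2 scores (the
scoring surface is pluggable but only BIC is implemented), no
equivalence-class-aware SHD, and no soft/probabilistic priors — constraints
here are deterministic statements, enforced exactly.
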