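# Methods

This note documents the models and algorithms behind `metnet`, the design
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## Model representation

A reaction stores one signed stoichiometry map (substrates negative,
products positive) plus a reversibility flag; the reaction is never
duplicated into two directions at the model level. Consequences:

- A species appearing on both sides of an SBML reaction is netted at
  ingestion; a zero net coefficient drops the species from the reaction.
  Stoichiometric *quantities* only matter for display anyway — every graph
  construction and the reachability logic use presence/absence.
- Exchange reactions (one empty side) are representable and needed: drains
  let the reachability expansion start, and genome-scale models are full of
  them.
- Reaction ids and metabolite ids must be disjoint, because graph vertices
  inherit model ids unchanged and a vertex is identified by (id, type).

SBML reading (via libsbml) uses only species, reactant/product lists,
`reversible` and `boundaryCondition`; kinetic laws, gene associations and
flux bounds are ignored. The tabular dialect (`id<TAB>equation`, arrows
`<=>`/`->`, numeric coefficient prefixes, `#` comments) exists so tests,
docs and pipelines need no XML; it round-trips through
`write_table_model`/`read_table_model`.

## Network construction

All three representations materialize reversibility as parallel directed
edges in opposite directions. Set labels (`fwd:<rid>`/`rev:<rid>`) are
assigned only in RC networks, and only for reversible reactions;
irreversible edges are unlabeled. Choices:

- **RR self-loops** (a reversible reaction feeding itself through its own
  reverse) are omitted by default — biologically vacuous, and they distort
  degree statistics — restorable with `self_loops=True`.
- **CC deduplication**: several reactions connecting the same metabolite
  pair yield one edge whose metadata lists the supporting reaction ids.
- **Ego subgraphs** expand undirected (a neighbor is a neighbor whether it
  feeds or is fed by the center): for the visualization use case, cutting
  off upstream context would be more surprising than including it. Radius
  is capped at 5.

Networks are multidigraphs (a metabolite interacting with a reversible
reaction in both directions genuinely carries parallel same-direction edges
with different set labels). The JSON persistence format
(`{representation, provenance, vertices:[...], edges:[...]}`, sorted keys,
lexicographic element order) is the interchange surface between CLI steps
and is byte-stable for diffing.

## Set-constrained breadth-first search

Rule: a path entering a vertex through an edge of a labeled set must leave
through an edge of the same set or an unlabeled edge. Entering through an
unlabeled edge leaves the exit unconstrained.

The search returns shortest **simple** paths under the rule. This is a
deliberate choice: pure state-space BFS over (vertex, entering-set) pairs
computes shortest constrained *walks*, and on networks with several
reversible reactions a shortest walk can revisit a metabolite under a
different set and undercut every rule-respecting simple path. A path
analysis that reports "A reaches B in 6 steps" on the strength of a walk
that threads the same metabolite twice is not what the method is for, so
walks are excluded.

Implementation: breadth-first expansion of stored paths (the storage cost
is intrinsic — this is what makes the constrained search more
memory-expensive than plain BFS), made exact-and-tractable by dominance
pruning. A frontier entry at state (vertex, entering-set) is discarded when
an earlier entry at the same state — shorter or equal, and lexicographically
no larger — visited a subset of its vertices: anything the discarded entry
could still reach, the earlier one can too. For point-to-point queries the
frontier is a priority queue keyed on (length, path), which makes the first
settled target the lexicographically smallest among the shortest valid
paths; tie-breaking is therefore bit-reproducible. Worst-case behaviour is
exponential (shortest simple path under edge constraints is not a
polynomial problem in general); on bipartite RC networks with currency
metabolites filtered out the dominance record stays small in practice.

On CC/RR networks no set labels exist and SBBFS degrades to plain BFS with
a warning — these representations are path-unsafe by construction (a CC/RR
path may use two edges contributed by the same reaction), and the warning
keeps that caveat visible.

## Global path metrics

Diameter and mean shortest path run over all *ordered* pairs (u, v), u ≠ v,
v reachable from u — ordered because the graphs are directed. A network
with no connected pair reports zeros with `connected_pair_count = 0` rather
than erroring, so batch pipelines need no special casing.

## Rankings

- **DEGREE**: total (or in/out) degree on the multigraph — parallel edges
  count, consistent with the degree report.
- **BETWEENNESS**: directed, unnormalized Brandes pair dependencies
  (networkx implementation) on the simple-digraph view; `normalized=True`
  optional. Paths are plain BFS paths: pair dependencies of the
  constrained simple-path search do not decompose the way Brandes requires,
  so a constrained betweenness is not offered.
- **CLOSENESS**: for each vertex, (number of reachable other vertices) /
  (sum of outgoing distances to them), 0 when nothing is reachable. This
  keeps scores finite and comparable on the weakly connected, partially
  reachable graphs metabolism produces.
- **HITS**: hand-written power iteration on the simple-digraph adjacency,
  L2 normalization each half-step, tolerance 1e-8 (max absolute change of
  either vector), at most 1000 iterations; both hub and authority vectors
  are returned and the ranking is keyed on authority unless `by_hub`. A
  non-convergent run warns and returns the last iterate with
  `converged=False`.

Parallel edges are collapsed for the path-based methods and HITS: multiple
identical transitions change neither distances nor the qualitative "points
to" relation, but they would silently multiply path counts.

Tie-breaking in every ordering is lexicographic on id.

## Reachability (active vertices)

Monotone fixed point over *reaction directions*: direction d of reaction r
activates when all substrates of d are active; its products then become
active. Reversible reactions contribute two independent directions (the
reverse requires the products-as-written) — a reverse direction genuinely
consumes what the written direction produces; `directions="fwd-only"`
disables this. Directions with an empty substrate side fire at iteration 0.
Termination is guaranteed (finite universe, monotone growth); the result is
the least fixed point and independent of scan order, which the tests verify
against order-shuffled closures. The iteration trace (what was added when)
is kept for auditability, and `active_subnetwork` returns the induced RC
subgraph as a convenience.

## Filters

Threshold semantics are *remove high*: `filter_by_degree(threshold=k)`
removes degree ≥ k, `filter_by_ranking(min_score=s)` removes score ≥ s —
the use case is deleting currency metabolites, which are the high scorers.
Both are invertible (`keep_high`) and non-strict (≥), documented rather
than guessed silently. Top-n mode breaks degree ties lexicographically.
Isolated vertices are *not* auto-removed by any filter (`drop_isolated` is
its own step, as snapshot filtering shows it must be). All filters are
pure and compose: removing S₁ then S₂ equals removing S₁ ∪ S₂.

The currency-metabolite preset (ATP, ADP, AMP, NAD(H), NADP(H), H, H2O,
Pi, PPi, CO2) is a heuristic starting point, shipped as an editable text
file; there is no agreed definition of a currency metabolite and no
automatic detection is attempted.

## Simulation filtering and variation networks

Snapshot filtering compares |flux| < τ (strict) for removal; absolute value
because reversible reactions legitimately carry negative flux. Default
τ = 1e-9, a numerically safe zero for LP solver output. `signed=True`
restores raw-value comparison for the rare "remove backwards flux" use.

Variation networks select reaction vertices by (i) exclusivity — present in
exactly one snapshot — and/or (ii) flux variation — present in both with
|flux_b − flux_a| strictly exceeding a threshold. The percentage threshold
is interpreted relative to the *reference* condition's |flux_a| (the
natural "changed by X% of wild-type" reading); `pct_base="max"` offers
max(|a|, |b|) instead, and a zero base degrades to "any nonzero change".
Selected reactions are lifted out of the base network with their metabolite
neighbors and connecting edges (set labels inherited); every vertex carries
`tna_reason` (exclusive_a / exclusive_b / flux_change / participant) and
reactions carry `tna_flux_a`, `tna_flux_b`, `tna_delta`. Exclusivity and
flux change are disjoint by construction (flux change applies only to
shared reactions). Manual curation — dropping reactions known to be
irrelevant — is deliberately just `remove_vertices` on the result, not
automated.

Network comparison takes precomputed metrics (per-vertex dicts or global
scalars) for both sides and compares only the intersection of metric names;
vertices are matched on (id, type), which is sound for networks derived
from the same model and flagged with a warning otherwise.

## Export

XGMML attribute types (string/integer/real) are inferred from the Python
value so Cytoscape imports them typed; element order is lexicographic and
output is byte-deterministic. The XGMML reader exists to make the export
contract testable (write → read is the identity on vertices, edges, set
labels and metadata). Pajek `.net` stores topology only: 1-based indices in
lexicographic id order, arcs with weight 1, quotes in labels
backslash-escaped; metadata loss is inherent to the format.

## Fixture generator and what the tests show

The `diamond` fixture (R1: A + B <=> C reversible, R2: A → E, R3: E → B) is
the minimal topology on which plain and set-constrained search disagree,
and doubles as the worked example for snapshots and variation networks.
The `random` generator produces connected models with a requested reaction
count: a substrate→product backbone chain keeps the model connected, plus
0–2 extra participants per reaction and 40% reversibility — degree
structure and reversibility mix comparable to small hand-built pathway
models. Test suites use sizes 2–5 reactions (RC networks of ≤ 12 vertices)
so that exhaustive simple-path enumeration, path-counting betweenness and
dense eigendecompositions remain affordable oracles; suite sizes
(100 networks for the constrained-search check, 60 for centralities, 40
for reachability, 25–30 for exports and invariants) keep the whole
acceptance run around a second.

What passing does **not** show: behaviour on genome-scale inputs
(thousands of reactions) is exercised nowhere — the constrained search's
exponential worst case and the all-pairs metrics' quadratic cost both bite
there without prior currency filtering; the random generator does not
emulate compartments, biomass-style many-species reactions, or realistic
degree distributions (no scale-free hubs); and flux distributions are
hand-written, not produced by an LP solver, so solver-noise robustness
rests only on the τ = 1e-9 default.

Numerical notes: the HITS oracle comparison is restricted to graphs whose
top eigenvalue of AᵀA is simple with λ₂/λ₁ ≤ 0.98 — beyond that the
principal eigenvector is not unique (or power iteration cannot resolve it
to the 1e-6 comparison tolerance within its budget), and the check is
ill-posed rather than failed. Degree distributions are asserted to sum to
1 within 1e-12; closeness and betweenness oracles agree to 1e-12/1e-9.
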