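# metnet

Topological analysis of metabolic networks built from stoichiometric models,
with a bridge to constraint-based phenotype simulation: the package turns a
model into a graph, analyzes the graph, and — given the flux distributions
of two simulated conditions — extracts the compact subnetwork that explains
how a mutant's flux redistributed relative to the wild-type.

It is written for metabolic-engineering and systems-biology work where
strain-design algorithms propose knockout sets whose effect is spread over
dozens of reactions: genome-scale flux tables are unreadable, but the
*variation network* between two conditions usually is.

## What it does

**Models.** A stoichiometric model is a set of reactions with signed
stoichiometric coefficients (substrates negative, products positive) and a
reversibility flag. Models are read from SBML Level 2/3 or from a one-line-
per-reaction TSV dialect (`R1<TAB>A + B <=> C`); deterministic fixture
models are generated by `generate_fixture_model`.

**Three graph representations** of the same model:

- **RC** (reaction–compound): a directed bipartite graph; consumption edges
  point into reaction vertices, production edges out. A reversible reaction
  contributes parallel opposite edges in two labeled *sets*, `fwd:<rid>`
  and `rev:<rid>`.
- **CC** (compound–compound): metabolites only; an edge m₁ → m₂ whenever a
  reaction direction consumes m₁ and produces m₂.
- **RR** (reaction–reaction): reactions only; r₁ → r₂ whenever r₁ produces
  a metabolite r₂ consumes.

**Analysis.** Degree tables/histograms/distributions, neighbor lists,
radial (ego) subgraphs of radius 1–5, network diameter and mean shortest
path, and centrality rankings (degree, betweenness, closeness, HITS
hub/authority).

**Set-constrained shortest paths (SBBFS).** In an RC graph a plain BFS may
enter a reversible reaction through one direction's edge set and leave
through the other's, "crossing" the reaction between two same-side
metabolites — graph-valid, biochemically meaningless. The set-constrained
breadth-first search enforces: *a path entering a vertex through an edge of
a labeled set must leave through an edge of the same set or an unlabeled
edge*, and returns shortest simple paths under that rule.

**Reachability.** From a set of seed metabolites (e.g. the growth medium),
iteratively activate every reaction direction whose substrates are all
present and add its products, to a fixed point: the set of reactions that
can run and metabolites that can exist given unlimited seed supply.

**Filters.** Remove vertices by explicit list (a currency-metabolite preset
ships with the package), by degree threshold or top-n degree, or by
centrality score — the standard treatments for ubiquitous cofactors such as
ATP or H⁺ that would otherwise short-circuit every path.

**Simulation link.** Flux distributions (reaction → mmol/gCDW/h) filter a
network down to its flux-carrying "snapshot" (reactions with |v| below a
threshold removed, then orphaned metabolites). Two snapshots combine into a
**variation network**: reactions exclusive to one condition and/or
reactions whose |Δflux| exceeds a threshold (absolute or percentage), plus
their metabolite neighbors, every vertex tagged with the reason it is there
(`tna_reason`, `tna_flux_a`, `tna_flux_b`, `tna_delta`).

**Export.** XGMML (full metadata, Cytoscape-readable, with a reader for
round-trips) and Pajek `.net` (topology only).

## Worked example

The built-in `diamond` fixture model has four metabolites and three
reactions — `R1: A + B <=> C` (reversible), `R2: A -> E`, `R3: E -> B`:

```python
from metnet import (BFS, SBBFS, build_network, generate_fixture_model,
                    shortest_path)

rc = build_network(generate_fixture_model("diamond"), "RC")
print(shortest_path(rc, "A", "B", BFS).vertices)    # ['A', 'R1', 'B']
print(shortest_path(rc, "A", "B", SBBFS).vertices)  # ['A', 'R2', 'E', 'R3', 'B']
```

The BFS path (length 2) crosses R1 even though A and B are both its
substrates — they are consumed together, never converted into each other.
The set-constrained path (length 4) is the real conversion route through E.

Longer narrative scripts live in `examples/`; for instance
`python examples/snapshot_and_variation.py` prints

```
wild-type snapshot: 5 vertices, 4 edges (R1 and the orphaned C removed)
mutant snapshot:    7 vertices, 10 edges (everything active)
variation network: 7 vertices, 10 edges
  A   participant
  ...
  R1  exclusive_b   flux 0.0 -> 2.0  (delta +2.0)
  R2  flux_change   flux 1.0 -> 0.5  (delta -0.5)
```

i.e. the mutant switched R1 on (exclusive to condition b) and halved the
flux through the R2/R3 detour.

The same pipeline is scriptable from a shell via the thin `metnet` CLI
(`fixtures`, `build`, `degree`, `rank`, `path`, `distances`, `metrics`,
`reach`, `filter`, `simfilter`, `fluxcmp`, `netcmp`, `varnet`, `ego`,
`export`), with networks flowing between commands as JSON files.

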