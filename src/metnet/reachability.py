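"""Locate active vertices: fixed-point expansion from seed metabolites.

Starting from a set of "seed" metabolites assumed available in unlimited
supply, the expansion repeatedly activates every reaction direction whose
substrates are all present and adds its products, until nothing new can be
produced.  The result is the full set of reactions that can run and
metabolites that can exist in the system.  Stoichiometric quantities are
ignored — this is presence/absence logic, not flux — and a reversible
reaction contributes two independent directional rules (the reverse
direction requires the products-as-written).  A practical use is seeding
with the growth-medium components and reading off everything the model can
in principle synthesize from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError, VertexNotFoundError
from .model import MetabolicModel
from .netbuild import build_network, reaction_directions
from .network import MetabolicNetwork

__all__ = ["ReachabilityResult", "locate_active_vertices"]


@dataclass
class ReachabilityResult:
    """Outcome of the fixed-point expansion.

    ``active_reactions`` holds (reaction id, direction) pairs, direction
    being ``"fwd"`` or ``"rev"``; ``trace`` records, per iteration, the ids
    newly added (metabolites plus ``rid[direction]`` tags) for auditability.
    """

    seeds: frozenset[str]
    active_metabolites: set[str]
    active_reactions: set[tuple[str, str]]
    trace: list[tuple[int, list[str]]] = field(default_factory=list)

    @property
    def active_reaction_ids(self) -> set[str]:
        return {rid for rid, _ in self.active_reactions}

    def to_dict(self) -> dict:
        return {
            "seeds": sorted(self.seeds),
            "active_metabolites": sorted(self.active_metabolites),
            "active_reactions": [
                {"id": rid, "direction": d}
                for rid, d in sorted(self.active_reactions)
            ],
            "trace": [
                {"iteration": i, "added": added} for i, added in self.trace
            ],
        }


def locate_active_vertices(
    model: MetabolicModel,
    seeds,
    directions: str = "both",
) -> ReachabilityResult:
    """Expand from seed metabolites to the maximal active set.

    Parameters
    ----------
    model : MetabolicModel
    seeds : iterable of metabolite ids
        Must all exist in the model.
    directions : {"both", "fwd-only"}
        Whether reverse directions of reversible reactions may fire
        (default) or only the written direction.

    Notes
    -----
    A reaction direction with an empty substrate side (an exchange source)
    activates unconditionally at iteration 0.  Termination is guaranteed:
    the active sets grow monotonically inside a finite universe.
    """
    if directions not in ("both", "fwd-only"):
        raise UsageError(f"unknown directions option {directions!r}")
    seeds = frozenset(seeds)
    unknown = sorted(s for s in seeds if s not in set(model.metabolite_ids))
    if unknown:
        raise VertexNotFoundError("unknown seed metabolites: " + ", ".join(unknown))

    rules: list[tuple[str, str, frozenset[str], frozenset[str]]] = []
    for rxn in model.reactions:
        for direction, subs, prods in reaction_directions(rxn):
            if direction == "rev" and directions == "fwd-only":
                continue
            rules.append((rxn.id, direction, frozenset(subs), frozenset(prods)))

    active_mets = set(seeds)
    active_rxns: set[tuple[str, str]] = set()
    trace: list[tuple[int, list[str]]] = []
    iteration = 0
    while True:
        added: list[str] = []
        for rid, direction, subs, prods in rules:
            if (rid, direction) in active_rxns:
                continue
            if subs <= active_mets:
                active_rxns.add((rid, direction))
                added.append(f"{rid}[{direction}]")
                new_mets = prods - active_mets
                active_mets |= new_mets
                added.extend(sorted(new_mets))
        if not added:
            break
        trace.append((iteration, added))
        iteration += 1
    return ReachabilityResult(seeds, active_mets, active_rxns, trace)


def active_subnetwork(model: MetabolicModel, result: ReachabilityResult) -> MetabolicNetwork:
    """RC network induced on the active metabolites and reactions.

    Convenience view of a reachability result for export/visualization.
    """
    full = build_network(model, "RC")
    keep = result.active_metabolites | result.active_reaction_ids
    return full.induced_subgraph(
        keep, provenance=f"model:{model.id};active:{','.join(sorted(result.seeds))}"
    )
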