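"""Construct RC/CC/RR networks from a stoichiometric model.

Reversible reactions contribute, in every representation, parallel directed
edges in opposite directions.  In the RC (reaction-compound) representation
the two directions of a reversible reaction are tagged with *set labels*
``fwd:<rid>`` / ``rev:<rid>``; the set-constrained path search
(:func:`metnet.topology.shortest_path`) uses these labels to refuse paths
that enter and leave a reversible reaction on the same chemical side.
Irreversible edges carry no label.
"""

from __future__ import annotations

from .errors import UsageError, ValidationError, VertexNotFoundError
from .model import MetabolicModel, Reaction
from .network import METABOLITE, REACTION, MetabolicNetwork

__all__ = ["build_network", "ego_subgraph", "reaction_directions"]


def reaction_directions(rxn: Reaction):
    """Yield (direction, substrates, products) for each usable direction.

    Direction is ``"fwd"`` (as written) and, for reversible reactions,
    ``"rev"`` with substrate/product roles swapped.
    """
    subs = sorted(rxn.substrates)
    prods = sorted(rxn.products)
    yield "fwd", subs, prods
    if rxn.reversible:
        yield "rev", prods, subs


def _build_rc(model: MetabolicModel, net: MetabolicNetwork) -> None:
    for met in model.metabolites:
        net.add_vertex(
            met.id, METABOLITE,
            {"name": met.name, "compartment": met.compartment,
             "external": str(met.external).lower()},
        )
    for rxn in model.reactions:
        net.add_vertex(
            rxn.id, REACTION,
            {"name": rxn.name, "reversible": str(rxn.reversible).lower()},
        )
        for direction, subs, prods in reaction_directions(rxn):
            label = f"{direction}:{rxn.id}" if rxn.reversible else None
            for m in subs:
                net.add_edge(m, rxn.id, set_label=label)
            for m in prods:
                net.add_edge(rxn.id, m, set_label=label)


def _build_cc(model: MetabolicModel, net: MetabolicNetwork) -> None:
    for met in model.metabolites:
        net.add_vertex(met.id, METABOLITE, {"name": met.name})
    support: dict[tuple[str, str], set[str]] = {}
    for rxn in model.reactions:
        for _direction, subs, prods in reaction_directions(rxn):
            for s in subs:
                for p in prods:
                    if s != p:
                        support.setdefault((s, p), set()).add(rxn.id)
    for (s, p), rids in sorted(support.items()):
        net.add_edge(s, p, metadata={"reactions": ",".join(sorted(rids))})


def _build_rr(model: MetabolicModel, net: MetabolicNetwork,
              self_loops: bool = False) -> None:
    for rxn in model.reactions:
        net.add_vertex(rxn.id, REACTION, {"name": rxn.name})
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rxn in model.reactions:
        for _direction, subs, prods in reaction_directions(rxn):
            for m in subs:
                consumers.setdefault(m, set()).add(rxn.id)
            for m in prods:
                producers.setdefault(m, set()).add(rxn.id)
    pairs: dict[tuple[str, str], set[str]] = {}
    for m, prod_rxns in producers.items():
        for r1 in prod_rxns:
            for r2 in consumers.get(m, ()):
                if r1 == r2 and not self_loops:
                    continue
                pairs.setdefault((r1, r2), set()).add(m)
    for (r1, r2), mets in sorted(pairs.items()):
        if r1 == r2:
            # explicit opt-in: loop through nx directly (add_edge forbids them)
            net.graph.add_edge(
                r1, r2, set_label=None,
                metadata={"metabolites": ",".join(sorted(mets))},
            )
        else:
            net.add_edge(r1, r2, metadata={"metabolites": ",".join(sorted(mets))})


def build_network(
    model: MetabolicModel,
    representation: str = "RC",
    self_loops: bool = False,
) -> MetabolicNetwork:
    """Build a network in the given representation from a model.

    Parameters
    ----------
    model : MetabolicModel
        Source model; must contain at least one reaction.
    representation : {"RC", "CC", "RR"}
        Target representation (see :mod:`metnet.network`).
    self_loops : bool
        RR only: keep the r -> r loop a reversible reaction forms through
        its own reverse direction.  Off by default because such loops are
        biologically vacuous and distort degree statistics.
    """
    if representation not in ("RC", "CC", "RR"):
        raise UsageError(f"unknown representation {representation!r}")
    if not model.reactions:
        raise ValidationError("no reactions in model")
    net = MetabolicNetwork(representation, provenance=f"model:{model.id}")
    if representation == "RC":
        _build_rc(model, net)
    elif representation == "CC":
        _build_cc(model, net)
    else:
        _build_rr(model, net, self_loops=self_loops)
    return net


def ego_subgraph(
    net: MetabolicNetwork, center: str, radius: int = 1
) -> MetabolicNetwork:
    """Induced subgraph on all vertices within `radius` of `center`.

    Distance is measured on the undirected view of the network (a vertex is
    a neighbor whether it feeds or is fed by the center); the subgraph keeps
    every edge among the selected vertices.  The center is flagged in its
    metadata (``ego_center``).  Radius is limited to 1..5.
    """
    if not net.has_vertex(center):
        raise VertexNotFoundError(f"unknown vertex id {center!r}")
    if not 1 <= radius <= 5:
        raise UsageError(f"radius must be in 1..5, got {radius}")
    und = net.undirected_view()
    frontier = {center}
    keep = {center}
    for _ in range(radius):
        frontier = {w for v in frontier for w in und[v]} - keep
        if not frontier:
            break
        keep |= frontier
    sub = net.induced_subgraph(
        keep, provenance=f"{net.provenance};ego:{center},r={radius}"
    )
    sub.vertex_metadata(center)["ego_center"] = "true"
    return sub
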