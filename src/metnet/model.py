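"""Stoichiometric model containers.

A :class:`MetabolicModel` is the source of every network in this package: an
ordered collection of metabolites (with compartments and an external flag)
and reactions (signed stoichiometry plus a reversibility flag).  Substrates
carry negative coefficients and products positive ones, so each reaction is
stored in a single canonical orientation and reversibility is a flag rather
than a duplicated reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError, VertexNotFoundError

__all__ = ["Metabolite", "Reaction", "MetabolicModel"]


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a model.

    Parameters
    ----------
    id : str
        Unique identifier (unique within the model, and disjoint from
        reaction ids so a vertex id is unambiguous).
    name : str
        Human-readable name; defaults to the id.
    compartment : str
        Compartment label, e.g. ``"c"`` for cytosol.
    external : bool
        True for boundary/external species (medium components, sinks).
    """

    id: str
    name: str = ""
    compartment: str = ""
    external: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative
    for substrates, positive for products.  A reversible reaction is stored
    once, in its written direction, with ``reversible=True``.  An exchange
    reaction (pure source or sink) may have a one-sided stoichiometry.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if any(c == 0 for c in self.stoichiometry.values()):
            zeros = sorted(m for m, c in self.stoichiometry.items() if c == 0)
            raise ValidationError(
                f"reaction {self.id!r} has zero coefficients for {zeros}"
            )
        if not self.name:
            object.__setattr__(self, "name", self.id)

    @property
    def substrates(self) -> dict[str, float]:
        """Metabolite id -> |coefficient| for the consumed side as written."""
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        """Metabolite id -> coefficient for the produced side as written."""
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class MetabolicModel:
    """Ordered collection of metabolites and reactions.

    Iteration order is insertion order (deterministic); reaction and
    metabolite ids must be disjoint so that graph vertices inherit
    unambiguous identities.
    """

    def __init__(self, id: str = "model"):
        self.id = id
        self._metabolites: dict[str, Metabolite] = {}
        self._reactions: dict[str, Reaction] = {}

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        if met.id in self._reactions:
            raise ValidationError(
                f"metabolite id {met.id!r} collides with a reaction id"
            )
        self._metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        if rxn.id in self._metabolites:
            raise ValidationError(
                f"reaction id {rxn.id!r} collides with a metabolite id"
            )
        missing = sorted(set(rxn.stoichiometry) - set(self._metabolites))
        if missing:
            raise ValidationError(
                f"reaction {rxn.id!r} references undeclared metabolites: "
                + ", ".join(missing)
            )
        self._reactions[rxn.id] = rxn

    # -- access -----------------------------------------------------------

    @property
    def metabolites(self) -> list[Metabolite]:
        return list(self._metabolites.values())

    @property
    def reactions(self) -> list[Reaction]:
        return list(self._reactions.values())

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self._metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self._reactions)

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._metabolites[mid]
        except KeyError:
            raise VertexNotFoundError(f"unknown metabolite id {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._reactions[rid]
        except KeyError:
            raise VertexNotFoundError(f"unknown reaction id {rid!r}") from None

    def __contains__(self, some_id: str) -> bool:
        return some_id in self._metabolites or some_id in self._reactions

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self._metabolites == other._metabolites
            and self._reactions == other._reactions
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id!r}: {len(self._reactions)} reactions, "
            f"{len(self._metabolites)} metabolites>"
        )
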