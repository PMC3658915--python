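"""Model input: SBML, a tabular reaction dialect, and fixture generators.

The tabular dialect is a TSV with one reaction per line::

    R1<TAB>A + B <=> C
    PK<TAB>F6P + 2 ADP -> Pyr + 2 ATP

``<=>`` marks a reversible reaction, ``->`` an irreversible one; integer or
decimal prefixes are stoichiometric coefficients (default 1).  Either side
may be empty, which represents an exchange reaction (pure source or sink).
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import math
import os
import random
import re

from .errors import FormatError, UsageError, ValidationError
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_sbml_model",
    "read_table_model",
    "write_table_model",
    "generate_fixture_model",
]

_ARROWS = ("<=>", "->")
# term = optional numeric coefficient followed by a metabolite id
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def read_sbml_model(path: str | os.PathLike) -> MetabolicModel:
    """Read a stoichiometric model from an SBML Level 2/3 file.

    Only species, reactions (reactant/product stoichiometry) and the
    reversibility flag are used; kinetic laws, gene associations and flux
    bounds are ignored.  Species with ``boundaryCondition="true"`` are
    flagged external.

    Raises
    ------
    FormatError
        If the document is not well-formed SBML (first error line reported).
    ValidationError
        If a reaction references an undeclared species.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(err.getMessage().strip(), line=err.getLine())
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML document contains no model")

    model = MetabolicModel(sbml_model.getId() or "sbml_model")
    for sp in sbml_model.getListOfSpecies():
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment() or "",
                external=bool(sp.getBoundaryCondition()),
            )
        )
    declared = set(model.metabolite_ids)
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref, sign in ((rxn.getListOfReactants(), -1.0),
                          (rxn.getListOfProducts(), +1.0)):
            for sr in ref:
                sid = sr.getSpecies()
                if sid not in declared:
                    raise ValidationError(
                        f"reaction {rxn.getId()!r} references undeclared "
                        f"species {sid!r}"
                    )
                coef = sr.getStoichiometry()
                if coef is None or math.isnan(coef):
                    coef = 1.0
                stoich[sid] = stoich.get(sid, 0.0) + sign * coef
        # a species on both sides with equal coefficients nets to zero and
        # is dropped (the signed-map representation keeps net stoichiometry)
        stoich = {m: c for m, c in stoich.items() if c != 0}
        model.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or rxn.getId(),
                reversible=bool(rxn.getReversible()),
                stoichiometry=stoich,
            )
        )
    return model


def _parse_side(text: str, lineno: int) -> dict[str, float]:
    side: dict[str, float] = {}
    text = text.strip()
    if not text:
        return side
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise FormatError("empty term in equation", line=lineno)
        m = _TERM_RE.match(term)
        if m is None:
            raise FormatError(f"cannot parse term {term!r}", line=lineno)
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        side[met] = side.get(met, 0.0) + coef
    return side


def read_table_model(path: str | os.PathLike, model_id: str | None = None) -> MetabolicModel:
    """Read a model from the tabular reaction dialect (see module docstring).

    Metabolites are auto-registered on first mention, in order of
    appearance.  Duplicate reaction ids raise :class:`ValidationError`;
    a line without an arrow token raises :class:`FormatError` naming the
    line number.
    """
    if model_id is None:
        model_id = os.path.splitext(os.path.basename(str(path)))[0]
    model = MetabolicModel(model_id)
    seen_mets: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line:
                raise FormatError("expected id<TAB>equation", line=lineno)
            rid, equation = line.split("\t", 1)
            rid = rid.strip()
            if not rid:
                raise FormatError("empty reaction id", line=lineno)
            if rid in model.reaction_ids:
                raise ValidationError(f"duplicate reaction id {rid!r}")
            reversible = "<=>" in equation
            arrow = "<=>" if reversible else "->"
            if arrow not in equation:
                raise FormatError(
                    f"no arrow token ('<=>' or '->') in equation {equation!r}",
                    line=lineno,
                )
            lhs_text, rhs_text = equation.split(arrow, 1)
            lhs = _parse_side(lhs_text, lineno)
            rhs = _parse_side(rhs_text, lineno)
            stoich: dict[str, float] = {m: -c for m, c in lhs.items()}
            for m, c in rhs.items():
                stoich[m] = stoich.get(m, 0.0) + c
            stoich = {m: c for m, c in stoich.items() if c != 0}
            for met in list(lhs) + list(rhs):
                if met not in seen_mets:
                    model.add_metabolite(Metabolite(id=met))
                    seen_mets.add(met)
            model.add_reaction(
                Reaction(id=rid, stoichiometry=stoich, reversible=reversible)
            )
    return model


def _format_coef(c: float) -> str:
    if c == int(c):
        return str(int(c))
    return repr(c)


def _format_side(side: dict[str, float]) -> str:
    parts = []
    for met, coef in side.items():
        parts.append(met if coef == 1 else f"{_format_coef(coef)} {met}")
    return " + ".join(parts)


def write_table_model(model: MetabolicModel, path: str | os.PathLike) -> None:
    """Write a model in the tabular dialect; inverse of :func:`read_table_model`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# model: {model.id}\n")
        for rxn in model.reactions:
            arrow = "<=>" if rxn.reversible else "->"
            lhs = _format_side(rxn.substrates)
            rhs = _format_side(rxn.products)
            fh.write(f"{rxn.id}\t{lhs} {arrow} {rhs}".rstrip() + "\n")


def _diamond_model() -> MetabolicModel:
    """Four metabolites, three reactions, one reversible.

    R1: A + B <=> C couples A and B on the same side of a reversible
    reaction, while R2: A -> E and R3: E -> B provide the detour that a
    set-constrained path search must take from A to B.  This is the
    canonical worked example used throughout the tests and docs.
    """
    model = MetabolicModel("diamond")
    for mid in ("A", "B", "C", "E"):
        model.add_metabolite(Metabolite(id=mid))
    model.add_reaction(
        Reaction(id="R1", stoichiometry={"A": -1, "B": -1, "C": 1}, reversible=True)
    )
    model.add_reaction(Reaction(id="R2", stoichiometry={"A": -1, "E": 1}))
    model.add_reaction(Reaction(id="R3", stoichiometry={"E": -1, "B": 1}))
    return model


def _random_model(seed: int, size: int) -> MetabolicModel:
    """Connected random model with `size` reactions, reproducible from seed.

    A backbone chain M1 -> M2 -> ... keeps the model connected; extra
    substrates/products and reversibility are sampled on top of it.
    """
    if size < 2:
        raise UsageError("random fixture needs size >= 2")
    rng = random.Random(seed)
    n_mets = size + 1
    model = MetabolicModel(f"random_s{seed}_n{size}")
    met_ids = [f"M{i}" for i in range(1, n_mets + 1)]
    for mid in met_ids:
        model.add_metabolite(Metabolite(id=mid))
    for i in range(1, size + 1):
        stoich = {met_ids[i - 1]: -1.0, met_ids[i]: 1.0}
        # sprinkle extra participants without touching the backbone pair
        others = [m for m in met_ids if m not in stoich]
        rng.shuffle(others)
        for extra in others[: rng.randint(0, min(2, len(others)))]:
            stoich[extra] = rng.choice([-1.0, 1.0]) * rng.choice([1, 1, 2])
        model.add_reaction(
            Reaction(
                id=f"R{i}",
                stoichiometry=stoich,
                reversible=rng.random() < 0.4,
            )
        )
    return model


def generate_fixture_model(
    name: str = "diamond", seed: int = 0, size: int = 5
) -> MetabolicModel:
    """Generate a deterministic fixture model for tests and examples.

    ``name="diamond"`` returns the four-metabolite example (reversible
    R1: A + B <=> C plus the A -> E -> B detour); ``name="random"`` returns
    a connected model with `size` reactions reproducible from `seed`.
    """
    if name == "diamond":
        return _diamond_model()
    if name == "random":
        return _random_model(seed, size)
    raise UsageError(f"unknown fixture name {name!r} (expected 'diamond' or 'random')")
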