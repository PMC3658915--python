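"""Flux distributions: ingestion, snapshot filtering, and flux comparison.

A phenotype simulation (FBA, pFBA, a knockout mutant...) assigns each
reaction a flux in mmol/gCDW/h.  In a typical solution most reactions carry
no flux, so restricting the network to the flux-carrying reactions yields a
compact "snapshot" of the metabolism actually used under those conditions.
The snapshot filter removes reaction vertices whose |flux| falls below a
threshold, then the metabolites left without any incident edge.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, UsageError, ValidationError
from .network import METABOLITE, REACTION, MetabolicNetwork

__all__ = [
    "FluxDistribution",
    "FluxComparison",
    "read_flux_distribution",
    "write_flux_distribution",
    "filter_network_by_simulation",
    "compare_flux_distributions",
]


@dataclass
class FluxDistribution:
    """Labeled map reaction id -> flux value (mmol/gCDW/h)."""

    label: str
    fluxes: dict[str, float]

    def __post_init__(self):
        bad = sorted(r for r, v in self.fluxes.items() if not math.isfinite(v))
        if bad:
            raise ValidationError("non-finite flux for: " + ", ".join(bad))

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.fluxes.get(rid, default)


def read_flux_distribution(path: str | os.PathLike, label: str | None = None) -> FluxDistribution:
    """Read a two-column TSV ``reaction_id<TAB>flux`` (# comments allowed)."""
    if label is None:
        label = os.path.splitext(os.path.basename(str(path)))[0]
    fluxes: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("expected reaction_id<TAB>flux", line=lineno)
            rid, value = parts[0].strip(), parts[1].strip()
            if rid in fluxes:
                raise ValidationError(f"duplicate reaction id {rid!r}")
            try:
                fluxes[rid] = float(value)
            except ValueError:
                raise FormatError(f"non-numeric flux {value!r}", line=lineno) from None
    return FluxDistribution(label, fluxes)


def write_flux_distribution(dist: FluxDistribution, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# flux distribution: {dist.label}\n")
        for rid, v in dist.fluxes.items():
            fh.write(f"{rid}\t{v!r}\n")


def filter_network_by_simulation(
    net: MetabolicNetwork,
    fluxes: FluxDistribution,
    threshold: float = 1e-9,
    *,
    signed: bool = False,
    missing_zero: bool = False,
) -> MetabolicNetwork:
    """Reduce an RC network to its flux-carrying snapshot.

    Step 1 removes every reaction vertex whose flux magnitude is strictly
    below `threshold` (|flux| by default — reversible reactions carry
    negative flux when running backwards; `signed` compares the raw value
    instead).  Step 2 removes the metabolite vertices left with no incident
    edge.  Surviving reaction vertices are annotated with their flux value
    (metadata key ``flux``).

    Every reaction vertex must have a flux entry unless `missing_zero`
    treats absentees as zero flux.
    """
    if net.representation != "RC":
        raise UsageError("simulation filtering requires an RC network")
    if threshold < 0:
        raise UsageError("threshold must be >= 0")
    rxn_ids = net.vertices(REACTION)
    missing = sorted(r for r in rxn_ids if r not in fluxes.fluxes)
    if missing and not missing_zero:
        raise ValidationError(
            "no flux value for reactions: " + ", ".join(missing)
        )
    magnitude = (lambda v: v) if signed else abs
    doomed = [r for r in rxn_ids if magnitude(fluxes.get(r, 0.0)) < threshold]
    out = net.copy()
    out.graph.remove_nodes_from(doomed)
    isolated = [
        v for v in out.vertices(METABOLITE)
        if out.graph.in_degree(v) + out.graph.out_degree(v) == 0
    ]
    out.graph.remove_nodes_from(isolated)
    for r in out.vertices(REACTION):
        out.vertex_metadata(r)["flux"] = fluxes.get(r, 0.0)
    out.provenance = (
        f"{net.provenance};simfilter:{fluxes.label},threshold={threshold!r}"
    )
    return out


@dataclass
class FluxComparison:
    """Per-reaction comparison of two flux distributions.

    ``table`` columns: reaction_id, flux_a, flux_b, delta (= b - a),
    abs_delta, status (``both`` / ``missing_in_a`` / ``missing_in_b``).
    Rows cover the union of both maps; a missing flux counts as 0 and is
    flagged in status.
    """

    label_a: str
    label_b: str
    table: pd.DataFrame

    def sorted_by_change(self) -> pd.DataFrame:
        """Rows ordered by |delta| descending (bar-plot order), id as tiebreak."""
        return self.table.sort_values(
            ["abs_delta", "reaction_id"], ascending=[False, True]
        ).reset_index(drop=True)


def compare_flux_distributions(
    a: FluxDistribution, b: FluxDistribution
) -> FluxComparison:
    """One row per reaction in the union of both distributions."""
    rows = []
    for rid in sorted(set(a.fluxes) | set(b.fluxes)):
        in_a, in_b = rid in a.fluxes, rid in b.fluxes
        fa, fb = a.get(rid), b.get(rid)
        rows.append(
            {
                "reaction_id": rid,
                "flux_a": fa,
                "flux_b": fb,
                "delta": fb - fa,
                "abs_delta": abs(fb - fa),
                "status": "both" if in_a and in_b
                else ("missing_in_a" if not in_a else "missing_in_b"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["reaction_id", "flux_a", "flux_b", "delta", "abs_delta", "status"],
    )
    return FluxComparison(a.label, b.label, table)
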