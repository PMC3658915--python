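"""Vertex-removal filters: explicit lists, degree criteria, ranking thresholds.

Currency metabolites (ATP, NAD(H), protons, water...) take part in so many
reactions that they short-circuit path finding and dominate degree
statistics, so they are routinely removed before analysis.  There is no
agreed definition of a currency metabolite; these filters offer the usual
heuristics — an explicit id list (a preset ships with the package), a degree
threshold, the top-n highest-degree vertices, or a minimum centrality score.
All filters are pure: they return a new network and leave the input intact.
"""

from __future__ import annotations

import math
from importlib import resources

from .errors import UsageError, VertexNotFoundError
from .network import MetabolicNetwork
from .topology import rank_vertices

__all__ = [
    "remove_vertices",
    "filter_by_degree",
    "filter_by_ranking",
    "drop_isolated",
    "currency_metabolites",
]


def currency_metabolites() -> list[str]:
    """The shipped heuristic preset of ubiquitous cofactor ids."""
    text = (
        resources.files("metnet").joinpath("data/currency_metabolites.txt").read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def remove_vertices(
    net: MetabolicNetwork, ids, *, lenient: bool = False
) -> MetabolicNetwork:
    """Remove the listed vertices and all incident edges.

    Unknown ids raise :class:`VertexNotFoundError` listing every offender,
    unless `lenient` is set, in which case they are skipped.
    """
    ids = set(ids)
    unknown = sorted(v for v in ids if not net.has_vertex(v))
    if unknown and not lenient:
        raise VertexNotFoundError("unknown vertex ids: " + ", ".join(unknown))
    keep = set(net.graph.nodes()) - ids
    label = ",".join(sorted(ids - set(unknown))) or "(none)"
    return net.induced_subgraph(
        keep, provenance=f"{net.provenance};removed:{label}"
    )


def _in_scope(net: MetabolicNetwork, vtype_scope: str | None) -> list[str]:
    return net.vertices(vtype_scope)


def _degree_of(net: MetabolicNetwork, v: str, kind: str) -> int:
    g = net.graph
    if kind == "in":
        return g.in_degree(v)
    if kind == "out":
        return g.out_degree(v)
    if kind == "total":
        return g.in_degree(v) + g.out_degree(v)
    raise UsageError(f"unknown degree kind {kind!r}")


def filter_by_degree(
    net: MetabolicNetwork,
    *,
    threshold: int | None = None,
    top_n: int | None = None,
    degree_kind: str = "total",
    vtype_scope: str | None = None,
    keep_high: bool = False,
) -> MetabolicNetwork:
    """Remove vertices by degree, either above a threshold or the top n.

    Exactly one of `threshold` / `top_n` must be given.  Threshold mode
    removes every in-scope vertex whose `degree_kind` degree is >= the
    threshold (the currency-metabolite use case); `keep_high` inverts the
    predicate (removes degree < threshold).  Top-n mode removes the n
    in-scope vertices of highest degree, ties broken lexicographically by
    id.  `vtype_scope` restricts candidates to one vertex type.
    """
    if (threshold is None) == (top_n is None):
        raise UsageError("give exactly one of threshold= or top_n=")
    scope = _in_scope(net, vtype_scope)
    if threshold is not None:
        if threshold < 0:
            raise UsageError("threshold must be >= 0")
        if keep_high:
            doomed = [v for v in scope if _degree_of(net, v, degree_kind) < threshold]
        else:
            doomed = [v for v in scope if _degree_of(net, v, degree_kind) >= threshold]
        note = f"degree[{degree_kind}]{'<' if keep_high else '>='}{threshold}"
    else:
        if not 0 < top_n <= len(scope):
            raise UsageError(
                f"top_n must be in 1..{len(scope)} (in-scope vertices), got {top_n}"
            )
        ranked = sorted(
            scope, key=lambda v: (-_degree_of(net, v, degree_kind), v)
        )
        doomed = ranked[:top_n]
        note = f"top{top_n}[{degree_kind}]"
    out = remove_vertices(net, doomed)
    out.provenance = f"{net.provenance};degree-filter:{note}"
    return out


def filter_by_ranking(
    net: MetabolicNetwork,
    method: str,
    min_score: float,
    **rank_options,
) -> MetabolicNetwork:
    """Remove every vertex whose ranking score is >= `min_score`.

    High scorers are removed — the currency-metabolite use case, where the
    most central vertices are the ubiquitous cofactors.  `rank_options` are
    forwarded to :func:`metnet.topology.rank_vertices`.
    """
    if math.isinf(min_score) and min_score > 0:
        return net.copy(provenance=f"{net.provenance};rank-filter:none")
    ranking = rank_vertices(net, method, **rank_options)
    doomed = [v for v, s in ranking.scores.items() if s >= min_score]
    out = remove_vertices(net, doomed)
    out.provenance = f"{net.provenance};rank-filter:{method}>={min_score}"
    return out


def drop_isolated(net: MetabolicNetwork) -> MetabolicNetwork:
    """Remove vertices with no incident edges."""
    g = net.graph
    keep = [v for v in g.nodes() if g.in_degree(v) + g.out_degree(v) > 0]
    return net.induced_subgraph(keep, provenance=f"{net.provenance};drop-isolated")
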