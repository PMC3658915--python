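"""Typed directed graphs over reactions and metabolites.

:class:`MetabolicNetwork` wraps a :class:`networkx.MultiDiGraph` and adds the
typing discipline the domain needs: every vertex is a REACTION or a
METABOLITE, edges may carry a *set label* (the direction tag of a reversible
reaction, used by the set-constrained path search), and both vertices and
edges carry free-form metadata.  Three representations exist:

``RC``
    Reaction-compound: strict bipartite, consumption edges point into
    reaction vertices, production edges out of them.
``CC``
    Compound-compound: metabolite vertices only; an edge m1 -> m2 per
    reaction direction consuming m1 and producing m2 (deduplicated).
``RR``
    Reaction-reaction: reaction vertices only; an edge r1 -> r2 when some
    direction of r1 produces a metabolite some direction of r2 consumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import networkx as nx

from .errors import UsageError, ValidationError, VertexNotFoundError

__all__ = ["REACTION", "METABOLITE", "Edge", "MetabolicNetwork",
           "read_network_json", "write_network_json"]

REACTION = "REACTION"
METABOLITE = "METABOLITE"

Metadata = dict[str, "str | int | float"]


@dataclass(frozen=True)
class Edge:
    """A directed edge; ``set_label`` tags one direction of a reversible reaction."""

    source: str
    target: str
    set_label: str | None = None
    metadata: tuple = ()  # sorted (key, value) pairs; hashable

    @property
    def meta(self) -> Metadata:
        return dict(self.metadata)


def _freeze_meta(metadata: Metadata | None) -> tuple:
    return tuple(sorted((metadata or {}).items()))


class MetabolicNetwork:
    """A typed multidigraph in one of the RC/CC/RR representations."""

    def __init__(self, representation: str, provenance: str = ""):
        if representation not in ("RC", "CC", "RR"):
            raise UsageError(f"unknown representation {representation!r}")
        self.representation = representation
        self.provenance = provenance
        self.graph = nx.MultiDiGraph()

    # -- vertices ---------------------------------------------------------

    def add_vertex(self, vid: str, vtype: str, metadata: Metadata | None = None) -> None:
        if vtype not in (REACTION, METABOLITE):
            raise UsageError(f"unknown vertex type {vtype!r}")
        if self.representation == "CC" and vtype != METABOLITE:
            raise ValidationError("CC networks hold metabolite vertices only")
        if self.representation == "RR" and vtype != REACTION:
            raise ValidationError("RR networks hold reaction vertices only")
        if vid in self.graph:
            existing = self.graph.nodes[vid]["vtype"]
            if existing != vtype:
                raise ValidationError(
                    f"vertex {vid!r} already present with type {existing}"
                )
            return
        self.graph.add_node(vid, vtype=vtype, metadata=dict(metadata or {}))

    def has_vertex(self, vid: str) -> bool:
        return vid in self.graph

    def vertex_type(self, vid: str) -> str:
        self._require(vid)
        return self.graph.nodes[vid]["vtype"]

    def vertex_metadata(self, vid: str) -> Metadata:
        self._require(vid)
        return self.graph.nodes[vid]["metadata"]

    def vertices(self, vtype: str | None = None) -> list[str]:
        """Vertex ids in lexicographic order, optionally restricted by type."""
        ids = (
            v for v, d in self.graph.nodes(data=True)
            if vtype is None or d["vtype"] == vtype
        )
        return sorted(ids)

    def _require(self, vid: str) -> None:
        if vid not in self.graph:
            raise VertexNotFoundError(f"unknown vertex id {vid!r}")

    # -- edges ------------------------------------------------------------

    def add_edge(
        self,
        source: str,
        target: str,
        set_label: str | None = None,
        metadata: Metadata | None = None,
    ) -> None:
        self._require(source)
        self._require(target)
        if source == target:
            raise ValidationError(f"self-loop on {source!r} not allowed")
        if self.representation == "RC":
            if self.graph.nodes[source]["vtype"] == self.graph.nodes[target]["vtype"]:
                raise ValidationError(
                    f"RC edge {source!r}->{target!r} joins two vertices of the "
                    "same type (bipartite violation)"
                )
        self.graph.add_edge(
            source, target, set_label=set_label, metadata=dict(metadata or {})
        )

    def edges(self) -> list[Edge]:
        """All edges, deterministically ordered (source, target, set label)."""
        out = [
            Edge(u, v, d.get("set_label"), _freeze_meta(d.get("metadata")))
            for u, v, d in self.graph.edges(data=True)
        ]
        out.sort(key=lambda e: (e.source, e.target, e.set_label or "", e.metadata))
        return out

    # -- views ------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def simple_digraph(self) -> nx.DiGraph:
        """Collapse parallel edges; used by centrality rankings."""
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes())
        g.add_edges_from((u, v) for u, v, _ in self.graph.edges(keys=True))
        return g

    def undirected_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes())
        g.add_edges_from((u, v) for u, v, _ in self.graph.edges(keys=True))
        return g

    def copy(self, provenance: str | None = None) -> "MetabolicNetwork":
        net = MetabolicNetwork(
            self.representation,
            self.provenance if provenance is None else provenance,
        )
        net.graph = self.graph.copy()
        return net

    def induced_subgraph(
        self, vertex_ids, provenance: str | None = None
    ) -> "MetabolicNetwork":
        """New network on the given vertices with all edges among them."""
        keep = set(vertex_ids)
        missing = sorted(keep - set(self.graph.nodes()))
        if missing:
            raise VertexNotFoundError("unknown vertex ids: " + ", ".join(missing))
        net = MetabolicNetwork(self.representation, provenance or self.provenance)
        net.graph = self.graph.subgraph(keep).copy()
        return net

    # -- comparison -------------------------------------------------------

    def _edge_multiset(self):
        from collections import Counter

        return Counter(
            (u, v, d.get("set_label"), _freeze_meta(d.get("metadata")))
            for u, v, d in self.graph.edges(data=True)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        if self.representation != other.representation:
            return False
        mine = {v: (d["vtype"], d["metadata"]) for v, d in self.graph.nodes(data=True)}
        theirs = {v: (d["vtype"], d["metadata"]) for v, d in other.graph.nodes(data=True)}
        return mine == theirs and self._edge_multiset() == other._edge_multiset()

    def __repr__(self) -> str:
        return (
            f"<MetabolicNetwork {self.representation}: {self.n_vertices} vertices, "
            f"{self.n_edges} edges>"
        )

    # -- JSON persistence -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "representation": self.representation,
            "provenance": self.provenance,
            "vertices": [
                {
                    "id": v,
                    "vtype": self.graph.nodes[v]["vtype"],
                    "metadata": self.graph.nodes[v]["metadata"],
                }
                for v in self.vertices()
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "set": e.set_label,
                    "metadata": e.meta,
                }
                for e in self.edges()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetabolicNetwork":
        net = cls(data["representation"], data.get("provenance", ""))
        for v in data["vertices"]:
            net.add_vertex(v["id"], v["vtype"], v.get("metadata") or {})
        for e in data["edges"]:
            net.add_edge(
                e["source"], e["target"], e.get("set"), e.get("metadata") or {}
            )
        return net


def write_network_json(net: MetabolicNetwork, path: str | os.PathLike) -> None:
    """Write the documented JSON layout with stable key ordering."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(net.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_network_json(path: str | os.PathLike) -> MetabolicNetwork:
    with open(path, encoding="utf-8") as fh:
        return MetabolicNetwork.from_dict(json.load(fh))
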