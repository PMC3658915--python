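"""Topological analysis: degrees, shortest paths, global metrics, rankings.

The distinctive piece here is the set-constrained breadth-first search
(SBBFS).  In an RC network a reversible reaction contributes two labeled
edge sets (``fwd:<rid>`` and ``rev:<rid>``).  A plain BFS may enter such a
reaction through one direction's edge and leave through the other's,
"crossing" the reaction between two metabolites that sit on the same
chemical side — a path that is graph-theoretically valid but biochemically
meaningless (the two metabolites are consumed or produced together, never
transformed into each other).  SBBFS enforces the rule that a path entering
a vertex through an edge of a labeled set must leave through an edge of the
same set or an unlabeled edge.  The search returns shortest *simple* paths:
it stores the path behind every frontier entry (which is what makes it more
memory-hungry than plain BFS), and a vertex may be reached again on another
branch under a different entering set — only repeats within one path are
forbidden.  Exactness is preserved by dominance pruning: a frontier entry is
dropped only when an earlier, shorter-or-equal entry at the same
(vertex, entering-set) state visited a subset of its vertices, and such an
entry can reach anything the dropped one could.

Example (the diamond fixture, RC representation): plain BFS finds
A -> R1 -> B (length 2) even though A and B are both substrates of R1;
SBBFS rejects it and returns A -> R2 -> E -> R3 -> B (length 4), the path a
biochemist would accept.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError, VertexNotFoundError
from .network import MetabolicNetwork

__all__ = [
    "BFS", "SBBFS",
    "DegreeReport", "PathResult", "GlobalPathMetrics", "RankingResult",
    "degree_report", "neighbors", "shortest_path", "single_source_distances",
    "global_path_metrics", "rank_vertices",
]

BFS = "BFS"
SBBFS = "SBBFS"

_RANK_METHODS = ("DEGREE", "BETWEENNESS", "CLOSENESS", "HITS")


# ---------------------------------------------------------------------------
# degree analysis

@dataclass
class DegreeReport:
    """Per-vertex degree table plus histogram and distribution.

    ``rows`` has columns id, vtype, in_degree, out_degree, total_degree;
    histogram maps degree -> vertex count and distribution maps degree ->
    fraction of vertices (sums to 1).
    """

    rows: pd.DataFrame
    histogram: dict[int, int]
    distribution: dict[int, float]
    degree_kind: str = "total"


def _degree_columns(net: MetabolicNetwork) -> pd.DataFrame:
    g = net.graph
    data = [
        {
            "id": v,
            "vtype": g.nodes[v]["vtype"],
            "in_degree": g.in_degree(v),
            "out_degree": g.out_degree(v),
            "total_degree": g.in_degree(v) + g.out_degree(v),
        }
        for v in net.vertices()
    ]
    return pd.DataFrame(data, columns=["id", "vtype", "in_degree", "out_degree",
                                       "total_degree"])


def degree_report(net: MetabolicNetwork, kind: str = "total") -> DegreeReport:
    """Degree table for every vertex, histogram and distribution.

    `kind` selects the degree used for the histogram/distribution
    (``"total"`` (default), ``"in"`` or ``"out"``); parallel edges from
    reversible reactions each count.
    """
    if net.n_vertices == 0:
        raise ValidationError("empty network")
    if kind not in ("total", "in", "out"):
        raise UsageError(f"unknown degree kind {kind!r}")
    rows = _degree_columns(net)
    col = {"total": "total_degree", "in": "in_degree", "out": "out_degree"}[kind]
    counts = rows[col].value_counts().sort_index()
    histogram = {int(k): int(v) for k, v in counts.items()}
    n = len(rows)
    distribution = {k: v / n for k, v in histogram.items()}
    return DegreeReport(rows, histogram, distribution, degree_kind=kind)


def neighbors(net: MetabolicNetwork, vertex: str) -> tuple[set[str], set[str]]:
    """(predecessors, successors) of a vertex."""
    if not net.has_vertex(vertex):
        raise VertexNotFoundError(f"unknown vertex id {vertex!r}")
    return set(net.graph.predecessors(vertex)), set(net.graph.successors(vertex))


# ---------------------------------------------------------------------------
# shortest paths

@dataclass
class PathResult:
    source: str
    target: str
    vertices: list[str]
    mode: str

    @property
    def length(self) -> int:
        return len(self.vertices) - 1


@dataclass
class GlobalPathMetrics:
    diameter: int
    mean_shortest_path: float
    connected_pair_count: int


def _check_mode(net: MetabolicNetwork, mode: str) -> str:
    if mode not in (BFS, SBBFS):
        raise UsageError(f"unknown path mode {mode!r}")
    if mode == SBBFS and net.representation != "RC":
        warnings.warn(
            f"set labels exist only in RC networks; SBBFS on a "
            f"{net.representation} network degrades to plain BFS",
            stacklevel=3,
        )
        return BFS
    return mode


def _out_edges(net: MetabolicNetwork):
    """vertex -> sorted list of (neighbor, set_label), parallel edges deduped."""
    table: dict[str, set[tuple[str, str | None]]] = {v: set() for v in net.graph}
    for u, v, d in net.graph.edges(data=True):
        table[u].add((v, d.get("set_label")))
    return {v: sorted(pairs, key=lambda p: (p[0], p[1] or "")) for v, pairs in table.items()}


def _allowed(entering: str | None, label: str | None) -> bool:
    # the set-exit rule: an unconstrained state or an unlabeled edge always
    # passes; otherwise the labels must match
    return entering is None or label is None or label == entering


def shortest_path(
    net: MetabolicNetwork, source: str, target: str, mode: str = BFS
) -> PathResult | None:
    """Minimum-edge-count path from source to target under the mode's rule.

    Among equal-length valid paths the lexicographically smallest vertex
    sequence is returned (deterministic output).  Returns ``None`` when no
    valid path exists.  ``mode=SBBFS`` applies the set-exit rule described
    in the module docstring; on non-RC networks it degrades to BFS with a
    warning.
    """
    for v in (source, target):
        if not net.has_vertex(v):
            raise VertexNotFoundError(f"unknown vertex id {v!r}")
    mode_eff = _check_mode(net, mode)
    if source == target:
        return PathResult(source, target, [source], mode)
    adj = _out_edges(net)
    # Search over stored simple paths with (length, path) priority: unit
    # weights make it a BFS, and the path tuple in the key makes the first
    # settled target the lexicographically smallest shortest path.  The
    # dominance record per (vertex, entering-set) state keeps the visited
    # sets already expanded there: a later arrival whose visited set
    # contains a recorded one can reach nothing the earlier (shorter-or-
    # equal, lexicographically smaller) arrival cannot, so it is pruned.
    heap: list[tuple[int, tuple[str, ...], str | None]] = [(0, (source,), None)]
    expanded: dict[tuple[str, str | None], list[frozenset[str]]] = {}
    while heap:
        dist, path, entering = heapq.heappop(heap)
        vertex = path[-1]
        if vertex == target:
            return PathResult(source, target, list(path), mode)
        visited = frozenset(path)
        state = (vertex, entering)
        seen = expanded.setdefault(state, [])
        if any(prev <= visited for prev in seen):
            continue
        seen.append(visited)
        for nxt, label in adj.get(vertex, ()):
            if nxt in visited:
                continue
            if mode_eff == SBBFS and not _allowed(entering, label):
                continue
            heapq.heappush(
                heap,
                (dist + 1, path + (nxt,), label if mode_eff == SBBFS else None),
            )
    return None


def single_source_distances(
    net: MetabolicNetwork, source: str, mode: str = BFS
) -> dict[str, int]:
    """Distances from `source` to every reachable vertex under the mode's rule.

    Unreachable vertices are omitted; the source itself maps to 0.
    """
    if not net.has_vertex(source):
        raise VertexNotFoundError(f"unknown vertex id {source!r}")
    mode_eff = _check_mode(net, mode)
    adj = _out_edges(net)
    if mode_eff == BFS:
        dist: dict[str, int] = {source: 0}
        queue: deque[str] = deque([source])
        while queue:
            vertex = queue.popleft()
            for nxt, _label in adj.get(vertex, ()):
                if nxt not in dist:
                    dist[nxt] = dist[vertex] + 1
                    queue.append(nxt)
        return dist
    # constrained mode: breadth-first over stored simple paths with
    # dominance pruning per (vertex, entering-set) state (see shortest_path)
    dist = {source: 0}
    expanded: dict[tuple[str, str | None], list[frozenset[str]]] = {}
    queue2: deque[tuple[frozenset[str], str, str | None, int]] = deque(
        [(frozenset({source}), source, None, 0)]
    )
    while queue2:
        visited, vertex, entering, d = queue2.popleft()
        state = (vertex, entering)
        seen = expanded.setdefault(state, [])
        if any(prev <= visited for prev in seen):
            continue
        seen.append(visited)
        for nxt, label in adj.get(vertex, ()):
            if nxt in visited or not _allowed(entering, label):
                continue
            if nxt not in dist:
                dist[nxt] = d + 1
            queue2.append((visited | {nxt}, nxt, label, d + 1))
    return dist


def global_path_metrics(net: MetabolicNetwork, mode: str = BFS) -> GlobalPathMetrics:
    """Diameter, mean shortest path and connected-pair count.

    Both metrics run over all *ordered* pairs (u, v), u != v, with v
    reachable from u under the mode's rule.  A network with no connected
    pair reports zeros (pair count 0).
    """
    if net.n_vertices == 0:
        raise ValidationError("empty network")
    diameter = 0
    total = 0
    pairs = 0
    for v in net.vertices():
        for target, d in single_source_distances(net, v, mode).items():
            if target == v:
                continue
            pairs += 1
            total += d
            diameter = max(diameter, d)
    mean = total / pairs if pairs else 0.0
    return GlobalPathMetrics(diameter, mean, pairs)


# ---------------------------------------------------------------------------
# rankings

@dataclass
class RankingResult:
    """Vertex scores for one ranking method plus a deterministic ordering.

    For HITS, ``scores`` holds the ranking key (authority by default) and
    ``hub_scores`` / ``authority_scores`` both full vectors; ``converged``
    is False when power iteration hit the iteration cap.
    """

    method: str
    scores: dict[str, float]
    ordering: list[str]
    hub_scores: dict[str, float] | None = None
    authority_scores: dict[str, float] | None = None
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": v, "score": self.scores[v]} for v in self.ordering]
        df = pd.DataFrame(rows, columns=["id", "score"])
        if self.hub_scores is not None:
            df["hubness"] = [self.hub_scores[v] for v in self.ordering]
            df["authority"] = [self.authority_scores[v] for v in self.ordering]
        return df


def _ordering(scores: dict[str, float]) -> list[str]:
    return sorted(scores, key=lambda v: (-scores[v], v))


def _closeness_scores(net: MetabolicNetwork) -> dict[str, float]:
    # reachable-count over distance-sum, outgoing distances; 0 for vertices
    # that reach nothing
    scores = {}
    for v in net.vertices():
        dist = single_source_distances(net, v, BFS)
        dist.pop(v, None)
        scores[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return scores


def _hits_scores(
    net: MetabolicNetwork, tol: float = 1e-8, max_iter: int = 1000
):
    import networkx as nx

    nodes = net.vertices()
    g = net.simple_digraph()
    a_mat = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    n = len(nodes)
    hub = np.full(n, 1 / np.sqrt(n))
    auth = np.full(n, 1 / np.sqrt(n))
    converged = False
    for _ in range(max_iter):
        new_auth = a_mat.T @ hub
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth /= norm
        new_hub = a_mat @ new_auth
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub /= norm
        if max(np.abs(new_auth - auth).max(), np.abs(new_hub - hub).max()) < tol:
            hub, auth = new_hub, new_auth
            converged = True
            break
        hub, auth = new_hub, new_auth
    hub_scores = {v: float(hub[i]) for i, v in enumerate(nodes)}
    auth_scores = {v: float(auth[i]) for i, v in enumerate(nodes)}
    return hub_scores, auth_scores, converged


def rank_vertices(
    net: MetabolicNetwork,
    method: str = "DEGREE",
    *,
    normalized: bool = False,
    by_hub: bool = False,
    degree_kind: str = "total",
) -> RankingResult:
    """Score every vertex by a centrality method and rank descending.

    Methods: ``DEGREE`` (total degree by default; `degree_kind` selects
    in/out/total), ``BETWEENNESS`` (directed Brandes pair dependencies,
    unnormalized unless `normalized`), ``CLOSENESS`` (reachable-count over
    distance-sum, outgoing), ``HITS`` (power iteration with L2
    normalization, tolerance 1e-8, at most 1000 iterations; ranked on
    authority unless `by_hub`).  Parallel edges are collapsed for the
    path-based methods and HITS; DEGREE counts them.  Ties in the ordering
    break lexicographically on id.
    """
    import networkx as nx

    if net.n_vertices == 0:
        raise ValidationError("empty network")
    if method not in _RANK_METHODS:
        raise UsageError(f"unknown ranking method {method!r}")
    hub_scores = auth_scores = None
    converged = True
    if method == "DEGREE":
        g = net.graph
        fn = {"total": lambda v: g.in_degree(v) + g.out_degree(v),
              "in": g.in_degree, "out": g.out_degree}
        if degree_kind not in fn:
            raise UsageError(f"unknown degree kind {degree_kind!r}")
        scores = {v: float(fn[degree_kind](v)) for v in net.vertices()}
    elif method == "BETWEENNESS":
        scores = {
            v: float(s)
            for v, s in nx.betweenness_centrality(
                net.simple_digraph(), normalized=normalized
            ).items()
        }
    elif method == "CLOSENESS":
        scores = _closeness_scores(net)
    else:  # HITS
        hub_scores, auth_scores, converged = _hits_scores(net)
        if not converged:
            warnings.warn("HITS did not converge within 1000 iterations")
        scores = dict(hub_scores if by_hub else auth_scores)
    return RankingResult(
        method=method,
        scores=scores,
        ordering=_ordering(scores),
        hub_scores=hub_scores,
        authority_scores=auth_scores,
        converged=converged,
    )
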