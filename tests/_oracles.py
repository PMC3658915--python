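"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, dense linear
algebra, order-shuffled fixed points) and shares no code path with the
package internals it checks.
"""

from __future__ import annotations

import math
import random
from collections import deque

import networkx as nx
import numpy as np

from metnet.network import MetabolicNetwork


def edge_list(net: MetabolicNetwork):
    """(source, target, set_label) triples, duplicates removed."""
    return sorted(
        {(u, v, d.get("set_label")) for u, v, d in net.graph.edges(data=True)},
        key=lambda t: (t[0], t[1], t[2] or ""),
    )


def out_edges_table(net: MetabolicNetwork):
    table: dict[str, list[tuple[str, str | None]]] = {v: [] for v in net.graph}
    for u, v, lab in edge_list(net):
        table[u].append((v, lab))
    return table


def set_rule_ok(entering: str | None, leaving: str | None) -> bool:
    return entering is None or leaving is None or leaving == entering


def constrained_simple_path_distances(net: MetabolicNetwork, source: str):
    """Min length over exhaustively enumerated vertex-simple paths that obey
    the set-exit rule.  Exponential; use only on tiny networks."""
    adj = out_edges_table(net)
    best = {source: 0}

    def dfs(v, entering, visited, depth):
        for w, label in adj[v]:
            if w in visited or not set_rule_ok(entering, label):
                continue
            if depth + 1 < best.get(w, math.inf):
                best[w] = depth + 1
            dfs(w, label, visited | {w}, depth + 1)

    dfs(source, None, {source}, 0)
    return best


def path_respects_set_rule(net: MetabolicNetwork, vertices: list[str]) -> bool:
    """True if SOME edge labeling of the vertex sequence obeys the rule."""
    adj = out_edges_table(net)

    def step(i, entering):
        if i == len(vertices) - 1:
            return True
        v, w = vertices[i], vertices[i + 1]
        return any(
            set_rule_ok(entering, lab) and step(i + 1, lab)
            for (x, lab) in adj[v]
            if x == w
        )

    return step(0, None)


def bfs_distances(net: MetabolicNetwork, source: str):
    adj = out_edges_table(net)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w, _ in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def all_shortest_paths(g: nx.DiGraph, s: str, t: str):
    """Enumerate all shortest s->t paths by walking the BFS layer DAG."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in g.successors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    if t not in dist:
        return

    def extend(path):
        v = path[-1]
        if v == t:
            yield list(path)
            return
        for w in g.successors(v):
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                yield from extend(path + [w])

    yield from extend([s])


def brute_betweenness(g: nx.DiGraph):
    """Unnormalized directed pair-dependency counts by path enumeration."""
    bc = {v: 0.0 for v in g.nodes()}
    for s in g.nodes():
        for t in g.nodes():
            if s == t:
                continue
            paths = list(all_shortest_paths(g, s, t))
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def brute_closeness(g: nx.DiGraph):
    """Reachable-count over outgoing-distance-sum, 0 when nothing reachable."""
    scores = {}
    for v in g.nodes():
        dist = nx.single_source_shortest_path_length(g, v)
        dist.pop(v, None)
        scores[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return scores


def hits_authority_eig(net: MetabolicNetwork):
    """Principal eigenvector of A^T A by dense eigendecomposition.

    Returns None when the spectral gap is too small for the comparison to
    be well-posed: at a degenerate top eigenvalue the authority vector is
    not unique, and with lambda2/lambda1 near 1 power iteration cannot
    resolve the eigenvector to 1e-6 within its iteration budget.
    """
    nodes = net.vertices()
    g = net.simple_digraph()
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    w, v = np.linalg.eigh(a.T @ a)
    if len(w) >= 2 and (w[-1] <= 0 or w[-2] / w[-1] > 0.98):
        return None
    vec = np.abs(v[:, -1])
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return dict(zip(nodes, vec))


def project_rc_to_cc_edges(rc: MetabolicNetwork):
    """CC edge set implied by an RC network: m1->m2 iff some reaction vertex
    has in-edge from m1 and out-edge to m2 with the same set label."""
    edges = set()
    for r in rc.vertices("REACTION"):
        ins = {(u, lab) for u, v, lab in edge_list(rc) if v == r}
        outs = {(v, lab) for u, v, lab in edge_list(rc) if u == r}
        for m1, l1 in ins:
            for m2, l2 in outs:
                if l1 == l2 and m1 != m2:
                    edges.add((m1, m2))
    return edges


def project_rc_to_rr_edges(rc: MetabolicNetwork):
    """RR edge set implied by an RC network: r1->r2 iff some metabolite is
    produced by r1 (any direction) and consumed by r2 (any direction)."""
    edges = set()
    for m in rc.vertices("METABOLITE"):
        producers = {u for u, v, _ in edge_list(rc) if v == m}  # edges r -> m
        consumers = {v for u, v, _ in edge_list(rc) if u == m}  # edges m -> r
        for r1 in producers:
            for r2 in consumers:
                if r1 != r2:
                    edges.add((r1, r2))
    return edges


def reachability_closure(model, seeds, rng: random.Random):
    """Order-shuffled one-rule-at-a-time fixed point over reaction directions."""
    rules = []
    for rxn in model.reactions:
        rules.append((rxn.id, "fwd", frozenset(rxn.substrates), frozenset(rxn.products)))
        if rxn.reversible:
            rules.append((rxn.id, "rev", frozenset(rxn.products), frozenset(rxn.substrates)))
    rng.shuffle(rules)
    mets = set(seeds)
    fired: set[tuple[str, str]] = set()
    changed = True
    while changed:
        changed = False
        for rid, direction, subs, prods in rules:
            if (rid, direction) in fired:
                continue
            if subs <= mets:
                fired.add((rid, direction))
                mets |= prods
                changed = True
    return mets, fired
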