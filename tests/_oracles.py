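"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (Floyd–Warshall,
exhaustive shortest-path enumeration, pairwise neighbor counting,
big-integer hypergeometric summation, union-find) and deliberately
avoids the code paths — and the graph/statistics libraries — used by the
package itself.
"""

from __future__ import annotations

import math
from itertools import combinations

INF = float("inf")


def adjacency(edges, nodes):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def floyd_warshall(edges, nodes):
    nodes = list(nodes)
    dist = {v: {w: (0 if v == w else INF) for w in nodes} for v in nodes}
    for a, b in edges:
        if a != b:
            dist[a][b] = dist[b][a] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == INF:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def shortest_paths(adj, dist, s, t):
    """All shortest s-t paths as node lists, by DFS along the distance field."""
    if dist[s][t] == INF:
        return []
    paths = []

    def walk(node, acc):
        if node == t:
            paths.append(acc)
            return
        for nxt in adj[node]:
            if dist[nxt][t] == dist[node][t] - 1:
                walk(nxt, acc + [nxt])

    walk(s, [s])
    return paths


def betweenness(edges, nodes):
    """Normalized betweenness by exhaustive enumeration of shortest paths."""
    nodes = list(nodes)
    n = len(nodes)
    adj = adjacency(edges, nodes)
    dist = floyd_warshall(edges, nodes)
    raw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / sigma
    denom = (n - 1) * (n - 2) / 2
    if denom <= 0:
        return {v: 0.0 for v in nodes}
    return {v: raw[v] / denom for v in nodes}


def closeness(edges, nodes):
    dist = floyd_warshall(edges, nodes)
    return {v: 1.0 / sum(d for w, d in dist[v].items() if w != v)
            for v in nodes}


def radiality(edges, nodes):
    nodes = list(nodes)
    n = len(nodes)
    dist = floyd_warshall(edges, nodes)
    delta = max(dist[v][w] for v in nodes for w in nodes)
    return {
        v: sum(delta + 1 - dist[v][w] for w in nodes if w != v) / (n - 1)
        for v in nodes
    }


def clustering(edges, nodes):
    adj = adjacency(edges, nodes)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def topological(edges, nodes):
    adj = adjacency(edges, nodes)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k == 0:
            out[v] = 0.0
            continue
        js = []
        for w in nodes:
            if w == v:
                continue
            shared = len(adj[v] & adj[w])
            if shared > 0:
                js.append(shared + (1 if w in adj[v] else 0))
        out[v] = (sum(js) / len(js)) / k if js else 0.0
    return out


def neighborhood_connectivity(edges, nodes):
    adj = adjacency(edges, nodes)
    return {
        v: (sum(len(adj[w]) for w in adj[v]) / len(adj[v])) if adj[v] else 0.0
        for v in nodes
    }


def hypergeom_tail_exact(N, B, n, b):
    """P(X >= b) as an exact big-integer rational, then one float division."""
    hi = min(n, B)
    num = sum(math.comb(B, i) * math.comb(N - B, n - i) for i in range(b, hi + 1))
    return num / math.comb(N, n)


def components_union_find(edges, nodes):
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))
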