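"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the package: shortest paths come from a hand-rolled BFS, betweenness
from sigma-counting over the BFS distance structure, the eigenvector from a
dense eigendecomposition, and the matcher from a direct per-node criterion
scan without any traversal or indexing.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def brute_degree(adj: dict) -> dict:
    return {v: len(nbrs) for v, nbrs in adj.items()}


def brute_closeness(adj: dict) -> dict:
    """1 / (sum of distances), unreachable pairs contributing distance n."""
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values()) + n * (n - len(dist))
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def brute_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness, endpoints excluded, unordered pairs once.

    For each source s: sigma[v] = number of shortest s-v paths (computed by
    dynamic programming over BFS levels). Then for each unordered pair
    (s, t) and interior node v with d(s,v) + d(v,t) = d(s,t), v receives
    sigma_sv * sigma_vt / sigma_st.
    """
    nodes = list(adj)
    dist = {s: bfs_distances(adj, s) for s in nodes}
    sigma = {}
    for s in nodes:
        sig = {s: 1}
        order = sorted((d, v) for v, d in dist[s].items())
        for _, v in order:
            if v == s:
                continue
            sig[v] = sum(sig[u] for u in adj[v]
                         if u in dist[s] and dist[s][u] == dist[s][v] - 1)
        sigma[s] = sig
    out = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    out[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return out


def brute_eigenvector(adj: dict) -> dict:
    """Principal eigenvector of the largest component via dense eigh."""
    nodes = sorted(adj)
    out = {v: 0.0 for v in nodes}
    if not any(adj.values()):
        return out
    seen: set = set()
    components = []
    for v in nodes:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        components.append(comp)
    comp = max(components, key=lambda c: (len(c), min(c)))
    cn = sorted(comp)
    idx = {v: i for i, v in enumerate(cn)}
    a = np.zeros((len(cn), len(cn)))
    for v in cn:
        for u in adj[v]:
            a[idx[v], idx[u]] = 1.0
    w, vecs = np.linalg.eigh(a)
    x = vecs[:, np.argmax(w)]
    x = np.abs(x)
    x = x / np.linalg.norm(x)
    out.update(zip(cn, x.tolist()))
    return out


def brute_match(query_adj: dict, db_adj: dict, rho: float) -> set:
    """Every query node tested directly against the mismatch criterion.

    A node matches when it exists in the database and the number of its
    query neighbours that exist in the database but are not database
    neighbours is at most ceil(rho * query degree).
    """
    matched = set()
    for v, nbrs in query_adj.items():
        if v not in db_adj:
            continue
        missing = sum(1 for u in nbrs if u in db_adj and u not in db_adj[v])
        if missing <= math.ceil(rho * len(nbrs)):
            matched.add(v)
    return matched


def graph_to_adj(g) -> dict:
    return {v: set(g[v]) for v in g.nodes}
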