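"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness by
explicit shortest-path enumeration, Steiner connectors by exhaustive
subset search, hypergeometric tails by exact integer arithmetic and by
literal subset enumeration.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def bfs_dist(adj: dict, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths by DFS along strictly decreasing distance-to-t."""
    dist_t = bfs_dist(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(acc)
            return
        for v in adj[u]:
            if dist_t.get(v, math.inf) == dist_t[u] - 1:
                walk(v, acc + [v])

    walk(s, [s])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Unnormalised betweenness, endpoints excluded, fractional path credit."""
    nodes = sorted(adj)
    bt = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                bt[v] += share
    return bt


def seeds_connected(adj: dict, nodes: set, seeds: list) -> bool:
    """Are all seeds in one component of the induced subgraph on ``nodes``?"""
    sub = {u: [v for v in adj[u] if v in nodes] for u in nodes}
    reach = bfs_dist(sub, seeds[0])
    return all(s in reach for s in seeds)


def optimal_connector_count(adj: dict, seeds: list) -> int | None:
    """Minimum number of non-seed nodes whose addition connects all seeds.

    Exhaustive subset enumeration in increasing size; None when the
    seeds cannot be connected at all.
    """
    others = sorted(set(adj) - set(seeds))
    for size in range(len(others) + 1):
        for comb in itertools.combinations(others, size):
            if seeds_connected(adj, set(seeds) | set(comb), seeds):
                return size
    return None


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by exact integer combinatorics."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(n, K) + 1))
    return Fraction(num, math.comb(N, n))


def hypergeom_tail_enumerated(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by literal enumeration of all n-subsets (tiny N only)."""
    target = set(range(K))
    hits = sum(1 for comb in itertools.combinations(range(N), n)
               if len(target & set(comb)) >= k)
    return Fraction(hits, math.comb(N, n))


def graph_to_adj(g) -> dict:
    return {u: sorted(g.neighbors(u)) for u in g.nodes}
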