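"""Two-level map-equation community detection.

The map equation scores a partition M of a graph by the expected
per-step description length of an unweighted (degree-proportional)
random walk encoded with a two-level codebook:

    L(M) = q H(Q) + sum_i p_i H(P_i)

where q is the total inter-module transition rate, H(Q) the entropy of
module exit rates and H(P_i) the entropy of within-module visit and
exit rates.  In node/module quantities (with plogp(x) = x log2 x,
visit rate p_a = k_a / 2W, module exit rate q_i = cut_i / 2W):

    L(M) = plogp(q) - 2 sum_i plogp(q_i) + sum_i plogp(q_i + P_i)
           - sum_a plogp(p_a)

Only the first three terms depend on the partition, and they depend
only on module-level strength and cut, so the objective can be
optimised on aggregated graphs Louvain-style: greedy node moving until
no move lowers L, aggregation of modules into super-nodes, and
repetition until the codelength stops improving.  The final partition
is flat (two-level).  The optimiser is deterministic given its seed
(node visit order is the only randomised choice) and the codelength
trace is non-increasing across passes by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx

from ._rng import substream

__all__ = ["Partition", "map_equation", "detect_communities"]


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


@dataclass
class Partition:
    """A flat community partition with its map-equation codelength."""

    membership: dict[str, int]
    codelength: float
    trace: list[float] = field(default_factory=list)  # codelength after each pass

    @property
    def communities(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def _graph_arrays(g: nx.Graph):
    """Adjacency as dicts of weights; total strength 2W."""
    adj: dict = {u: {} for u in g.nodes}
    strength: dict = {u: 0.0 for u in g.nodes}
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if u == v:
            strength[u] += 2 * w
            adj[u][u] = adj[u].get(u, 0.0) + w
        else:
            adj[u][v] = adj[u].get(v, 0.0) + w
            adj[v][u] = adj[v].get(u, 0.0) + w
            strength[u] += w
            strength[v] += w
    return adj, strength, sum(strength.values())


def map_equation(g: nx.Graph, membership: dict) -> float:
    """Two-level map-equation codelength (bits per step) of a partition."""
    if set(membership) != set(g.nodes):
        raise ValueError("membership must cover exactly the graph's nodes")
    adj, strength, two_w = _graph_arrays(g)
    if two_w == 0:
        return 0.0
    mod_strength: dict = {}
    mod_cut: dict = {}
    for u in g.nodes:
        m = membership[u]
        mod_strength[m] = mod_strength.get(m, 0.0) + strength[u]
        mod_cut.setdefault(m, 0.0)
    for u, v, data in g.edges(data=True):
        if u != v and membership[u] != membership[v]:
            w = float(data.get("weight", 1.0))
            mod_cut[membership[u]] += w
            mod_cut[membership[v]] += w
    node_term = -sum(_plogp(k / two_w) for k in strength.values())
    return _codelength_from_stats(mod_strength, mod_cut, two_w, node_term)


def _codelength_from_stats(mod_strength, mod_cut, two_w, node_term) -> float:
    q = sum(mod_cut.values()) / two_w
    term = _plogp(q) + node_term
    for m, s in mod_strength.items():
        if s <= 0 and mod_cut[m] <= 0:
            continue
        qi = mod_cut[m] / two_w
        term += -2 * _plogp(qi) + _plogp(qi + s / two_w)
    return term


class _Level:
    """Greedy node-moving on one (possibly aggregated) graph."""

    def __init__(self, adj, strength, two_w, node_term, membership):
        self.adj = adj
        self.strength = strength
        self.two_w = two_w
        self.node_term = node_term
        self.membership = dict(membership)
        self.mod_strength: dict = {}
        self.mod_cut: dict = {}
        for u, s in strength.items():
            m = self.membership[u]
            self.mod_strength[m] = self.mod_strength.get(m, 0.0) + s
            self.mod_cut.setdefault(m, 0.0)
        for u, nbrs in adj.items():
            mu = self.membership[u]
            for v, w in nbrs.items():
                if u < v and self.membership[v] != mu:
                    self.mod_cut[mu] += w
                    self.mod_cut[self.membership[v]] += w

    def codelength(self) -> float:
        return _codelength_from_stats(self.mod_strength, self.mod_cut,
                                      self.two_w, self.node_term)

    def _delta(self, k_ext, k_tot, w_a, w_b, mod_a, mod_b) -> float:
        """Codelength change of moving a node from mod_a to mod_b."""
        two_w = self.two_w
        cut_a, s_a = self.mod_cut[mod_a], self.mod_strength[mod_a]
        cut_b, s_b = self.mod_cut.get(mod_b, 0.0), self.mod_strength.get(mod_b, 0.0)
        cut_a2 = cut_a - k_ext + 2 * w_a
        s_a2 = s_a - k_tot
        cut_b2 = cut_b + k_ext - 2 * w_b
        s_b2 = s_b + k_tot
        q_old = sum(self.mod_cut.values())
        q_new = q_old - k_ext + 2 * w_a + k_ext - 2 * w_b

        def mod_terms(cut, s):
            if s <= 0 and cut <= 0:
                return 0.0
            qi = cut / two_w
            return -2 * _plogp(qi) + _plogp(qi + s / two_w)

        delta = _plogp(q_new / two_w) - _plogp(q_old / two_w)
        delta += mod_terms(cut_a2, s_a2) - mod_terms(cut_a, s_a)
        delta += mod_terms(cut_b2, s_b2) - mod_terms(cut_b, s_b)
        return delta

    def _apply(self, node, k_ext, k_tot, w_a, w_b, mod_a, mod_b) -> None:
        self.mod_cut[mod_a] = self.mod_cut[mod_a] - k_ext + 2 * w_a
        self.mod_strength[mod_a] -= k_tot
        if self.mod_strength[mod_a] <= 0 and self.mod_cut[mod_a] <= 1e-12:
            del self.mod_strength[mod_a], self.mod_cut[mod_a]
        self.mod_cut[mod_b] = self.mod_cut.get(mod_b, 0.0) + k_ext - 2 * w_b
        self.mod_strength[mod_b] = self.mod_strength.get(mod_b, 0.0) + k_tot
        self.membership[node] = mod_b

    def optimise(self, rng, max_passes: int = 64) -> list[float]:
        """Repeated node-moving passes; returns the codelength trace."""
        nodes = sorted(self.adj)
        trace = [self.codelength()]
        for _ in range(max_passes):
            order = list(nodes)
            rng.shuffle(order)
            moved = False
            for node in order:
                mod_a = self.membership[node]
                selfw = self.adj[node].get(node, 0.0)
                k_tot = self.strength[node]
                k_ext = k_tot - 2 * selfw
                w_to: dict = {}
                for v, w in self.adj[node].items():
                    if v != node:
                        w_to[self.membership[v]] = w_to.get(self.membership[v], 0.0) + w
                w_a = w_to.get(mod_a, 0.0)
                best_mod, best_delta = mod_a, 0.0
                for mod_b in sorted(w_to, key=str):
                    if mod_b == mod_a:
                        continue
                    d = self._delta(k_ext, k_tot, w_a, w_to[mod_b], mod_a, mod_b)
                    if d < best_delta - 1e-12:
                        best_mod, best_delta = mod_b, d
                if best_mod != mod_a:
                    self._apply(node, k_ext, k_tot, w_a, w_to[best_mod], mod_a, best_mod)
                    moved = True
            trace.append(self.codelength())
            if not moved:
                break
        return trace


def detect_communities(g: nx.Graph, seed: int = 0) -> Partition:
    """Detect communities by greedy two-level map-equation minimisation.

    Louvain-style: node moving until convergence, module aggregation,
    repeat; the result is a flat partition.  Deterministic given
    ``seed``.  An edgeless graph yields the all-singleton partition
    with a warning.
    """
    nodes = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        warnings.warn("edgeless graph: returning all-singleton partition")
        return Partition({n: i for i, n in enumerate(nodes)}, 0.0, [0.0])

    adj, strength, two_w = _graph_arrays(g)
    node_term = -sum(_plogp(k / two_w) for k in strength.values() if k > 0)

    # current assignment of original nodes to modules
    membership = {n: n for n in nodes}
    trace: list[float] = []
    level_adj, level_strength = adj, strength
    level_members = {n: {n} for n in nodes}  # module -> original nodes
    for _level in range(32):
        lev = _Level(level_adj, level_strength, two_w, node_term,
                     {u: u for u in level_adj})
        rng = substream(seed, "mapeq", _level)
        lev_trace = lev.optimise(rng)
        trace.extend(lev_trace if not trace else lev_trace[1:])
        groups: dict = {}
        for u, m in lev.membership.items():
            groups.setdefault(m, set()).add(u)
        if len(groups) == len(level_adj):
            break  # no merge at this level: converged
        # aggregate
        new_members = {}
        new_adj: dict = {}
        new_strength: dict = {}
        rep = {m: min(map(str, ms)) for m, ms in groups.items()}
        for m, ms in groups.items():
            r = rep[m]
            new_members[r] = set().union(*(level_members[u] for u in ms))
            new_adj[r] = {}
            new_strength[r] = sum(level_strength[u] for u in ms)
        node_to_rep = {u: rep[m] for m, ms in groups.items() for u in ms}
        for u, nbrs in level_adj.items():
            ru = node_to_rep[u]
            for v, w in nbrs.items():
                rv = node_to_rep[v]
                if u == v:
                    new_adj[ru][ru] = new_adj[ru].get(ru, 0.0) + w
                elif str(u) < str(v):
                    if ru == rv:
                        new_adj[ru][ru] = new_adj[ru].get(ru, 0.0) + w
                    else:
                        new_adj[ru][rv] = new_adj[ru].get(rv, 0.0) + w
                        new_adj[rv][ru] = new_adj[rv].get(ru, 0.0) + w
        level_adj, level_strength, level_members = new_adj, new_strength, new_members

    # flatten to original nodes with dense community ids
    final_membership = {}
    for cid, (r, members) in enumerate(sorted(level_members.items(), key=lambda kv: str(kv[0]))):
        for n in members:
            final_membership[n] = cid
    part = Partition(final_membership, trace[-1], trace)
    return part
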