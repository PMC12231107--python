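"""Seed-gene network inference on a confidence-scored interactome.

The pipeline maps screen hits ("seed" genes) onto a STRING-style
interactome filtered at high confidence (combined score >= 900 by
default) with required experimental evidence, then extracts either

* a first-order network (seeds plus all their direct neighbours), or
* a minimum network: the smallest connector-augmented subnetwork
  joining all seeds — a Steiner-tree problem approximated with the
  Takahashi–Matsuyama incremental shortest-path heuristic (unit edge
  lengths, deterministic lexicographic tie-breaking, 2-approximation
  guarantee on the tree cost).

Per-node degree and betweenness centrality (Brandes, unweighted,
unnormalised, endpoints excluded) rank the extracted nodes; community
structure comes from the map-equation optimiser in :mod:`chemnet.mapeq`
and its statistical significance from a degree-preserving
edge-rewiring null model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numba
import numpy as np
import pandas as pd

from ._rng import substream
from .io import read_edge_tsv
from .mapeq import Partition, detect_communities

__all__ = [
    "Subnetwork", "load_interactome", "first_order_network",
    "minimum_network", "centralities", "detect_communities",
    "community_significance",
]

log = logging.getLogger(__name__)


def normalize_id(gene: str) -> str:
    """Gene ids are opaque, case-normalized strings."""
    return str(gene).strip().upper()


@dataclass
class Subnetwork:
    """A seed-flagged subgraph of the interactome with analysis annotations."""

    graph: nx.Graph
    seeds: set[str]
    unmapped_seeds: list[str] = field(default_factory=list)
    isolated_seeds: list[str] = field(default_factory=list)
    partition: Partition | None = None
    community_p: dict[int, float] | None = None

    @property
    def connectors(self) -> set[str]:
        return set(self.graph.nodes) - self.seeds

    def node_table(self) -> pd.DataFrame:
        """Per-node summary: seed flag, degree, betweenness, community, p."""
        deg, btw = centralities(self)
        rows = []
        for node in sorted(self.graph.nodes):
            cid = self.partition.membership.get(node) if self.partition else None
            p = self.community_p.get(cid) if (self.community_p and cid is not None) else None
            rows.append((node, node in self.seeds, deg[node], btw[node], cid, p))
        return pd.DataFrame(rows, columns=["node", "is_seed", "degree",
                                           "betweenness", "community", "community_p"])


# ---------------------------------------------------------------------------
# Loading and filtering
# ---------------------------------------------------------------------------

def load_interactome(path: str | Path, min_combined: int = 900,
                     require_experimental: bool = True) -> nx.Graph:
    """Load a STRING-like edge table and apply the confidence filter.

    Keeps edges with combined_score >= ``min_combined`` and, when
    ``require_experimental``, experimental-channel score > 0.  Edges
    listed in both orientations are stored once (max scores kept);
    self-loops are dropped.  Logs edge counts before and after.
    """
    df = read_edge_tsv(path)
    for col in ("experimental", "combined_score"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}:{lineno}: non-integer {col!r} value")
        if ((vals < 0) | (vals > 1000)).any():
            lineno = int(((vals < 0) | (vals > 1000)).idxmax()) + 2
            raise ValueError(f"{path}:{lineno}: {col!r} outside [0, 1000]")
        df[col] = vals.astype(int)

    n_before = len(df)
    keep = df["combined_score"] >= min_combined
    if require_experimental:
        keep &= df["experimental"] > 0
    df = df[keep]

    g = nx.Graph()
    for p1, p2, exp, comb in df[["protein1", "protein2", "experimental",
                                 "combined_score"]].itertuples(index=False):
        u, v = normalize_id(p1), normalize_id(p2)
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["experimental"] = max(g[u][v]["experimental"], exp)
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], comb)
        else:
            g.add_edge(u, v, experimental=int(exp), combined_score=int(comb))
    log.info("interactome: %d input edges, %d after confidence filter, "
             "%d unique", n_before, int(keep.sum()), g.number_of_edges())
    if g.number_of_edges() == 0:
        warnings.warn("interactome is empty after confidence filtering")
    return g


def _map_seeds(g: nx.Graph, seeds) -> tuple[list[str], list[str]]:
    """Case-insensitively map seed ids to graph node labels."""
    lookup = {normalize_id(n): n for n in g.nodes}
    mapped, unmapped = [], []
    for s in sorted({normalize_id(s) for s in seeds}):
        if s in lookup:
            mapped.append(lookup[s])
        else:
            unmapped.append(s)
    if not mapped:
        raise ValueError("no seed maps to the interactome")
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Subnetwork extraction
# ---------------------------------------------------------------------------

def first_order_network(g: nx.Graph, seeds) -> Subnetwork:
    """Seeds plus their direct neighbours, with all induced edges."""
    if not seeds:
        raise ValueError("seed list is empty")
    mapped, unmapped = _map_seeds(g, seeds)
    nodes = set(mapped)
    for s in mapped:
        nodes.update(g.neighbors(s))
    sub = g.subgraph(nodes).copy()
    isolated = [s for s in mapped if sub.degree(s) == 0]
    return Subnetwork(sub, set(mapped), unmapped, isolated)


def _lexicographic_bfs(g: nx.Graph, sources: set[str]):
    """Multi-source BFS returning (dist, parent) with smallest-id parents.

    Visiting order within each BFS level is lexicographic, so the
    parent pointers (and hence extracted shortest paths) are unique and
    deterministic.
    """
    dist = {s: 0 for s in sources}
    parent: dict[str, str | None] = {s: None for s in sources}
    frontier = sorted(sources)
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(g.neighbors(u)):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    nxt.append(v)
        frontier = sorted(set(nxt))
    return dist, parent


def minimum_network(g: nx.Graph, seeds) -> Subnetwork:
    """Smallest connector-augmented subnetwork joining the seeds.

    Takahashi–Matsuyama heuristic per seed component: starting from the
    lexicographically smallest seed, repeatedly attach the unconnected
    seed closest to the growing tree via its shortest path (unit edge
    lengths; ties broken by node id).  Seeds falling in different
    connected components of the interactome yield one tree each.  The
    output graph is the union of the trees' nodes with all induced
    interactome edges; no non-seed node of tree-degree <= 1 remains.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    mapped, unmapped = _map_seeds(g, seeds)
    seed_set = set(mapped)

    components: dict[int, list[str]] = {}
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = i
    for s in mapped:
        components.setdefault(comp_of[s], []).append(s)

    tree = nx.Graph()
    for comp_seeds in (sorted(v) for _, v in sorted(components.items())):
        in_tree = {comp_seeds[0]}
        tree.add_node(comp_seeds[0])
        remaining = set(comp_seeds[1:])
        while remaining:
            dist, parent = _lexicographic_bfs(g, in_tree)
            target = min(remaining, key=lambda s: (dist[s], s))
            path = [target]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            for a, b in zip(path, path[1:]):
                tree.add_edge(a, b)
            in_tree.update(path)
            remaining.discard(target)

    # Prune any non-seed tree leaf (defensive: the heuristic's paths end
    # at seeds, so none should exist).
    changed = True
    while changed:
        changed = False
        for n in [n for n in tree.nodes if n not in seed_set and tree.degree(n) <= 1]:
            tree.remove_node(n)
            changed = True

    sub = g.subgraph(tree.nodes).copy()
    isolated = [s for s in mapped if s in sub and sub.degree(s) == 0]
    return Subnetwork(sub, seed_set, unmapped, isolated)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def centralities(s: Subnetwork | nx.Graph) -> tuple[dict[str, int], dict[str, float]]:
    """Per-node degree and Brandes betweenness (unweighted, unnormalised).

    Betweenness counts, for every ordered source/target pair, the
    fraction of shortest paths through the node; endpoints are excluded
    and equal-length paths share credit fractionally.
    """
    g = s.graph if isinstance(s, Subnetwork) else s
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    return degree, betweenness


# ---------------------------------------------------------------------------
# Community significance
# ---------------------------------------------------------------------------

def _internal_counts(edges_idx: np.ndarray, member_idx: np.ndarray,
                     n_comm: int) -> np.ndarray:
    """Internal edge count per community id, vectorised over the edge list."""
    cu = member_idx[edges_idx[:, 0]]
    cv = member_idx[edges_idx[:, 1]]
    same = cu == cv
    return np.bincount(cu[same], minlength=n_comm)


@numba.njit(cache=True)
def _swap_kernel(edges, adj, idx1, idx2, flips):  # pragma: no cover (jit)
    for i in range(idx1.shape[0]):
        e1, e2 = idx1[i], idx2[i]
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if flips[i]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if a == c and d == b:  # the two proposals are the same edge
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b


def _rewire(edges: list[tuple[int, int]], rng: np.random.Generator,
            n_attempts: int, n_nodes: int | None = None) -> list[tuple[int, int]]:
    """Degree-preserving double-edge swaps (fixed number of attempts).

    Proposals that would create a self-loop or a parallel edge are
    rejected, so the result is always a simple graph with the original
    degree sequence.
    """
    arr = np.array(edges, dtype=np.int64)
    m = arr.shape[0]
    n = n_nodes if n_nodes is not None else int(arr.max()) + 1
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[arr[:, 0], arr[:, 1]] = 1
    adj[arr[:, 1], arr[:, 0]] = 1
    idx1 = rng.integers(0, m, size=n_attempts)
    idx2 = rng.integers(0, m, size=n_attempts)
    flips = rng.random(n_attempts) < 0.5
    _swap_kernel(arr, adj, idx1, idx2, flips)
    return [tuple(e) for e in arr]


def community_significance(s: Subnetwork | nx.Graph, partition: Partition | dict,
                           n_null: int = 999, seed: int = 0) -> dict[int, float]:
    """Per-community p-value for internal-edge excess.

    Null model: degree-preserving double-edge rewiring of the whole
    graph (10 × |E| swap attempts per sample, fresh substream per
    sample).  p = (1 + #{null internal count >= observed}) / (n_null + 1).
    """
    if n_null < 19:
        raise ValueError("n_null < 19 gives too coarse a p-value resolution")
    g = s.graph if isinstance(s, Subnetwork) else s
    membership = partition.membership if isinstance(partition, Partition) else partition
    if set(membership) != set(g.nodes):
        raise ValueError("partition must cover exactly the graph's nodes")

    nodes = sorted(g.nodes)
    node_idx = {n: i for i, n in enumerate(nodes)}
    comm_ids = sorted(set(membership.values()))
    comm_idx = {c: i for i, c in enumerate(comm_ids)}
    member_idx = np.array([comm_idx[membership[n]] for n in nodes])
    edges = [(node_idx[u], node_idx[v]) for u, v in g.edges()]
    m = len(edges)
    if m == 0:
        return {c: 1.0 for c in comm_ids}

    edge_arr = np.array(edges, dtype=np.int64)
    base_adj = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    base_adj[edge_arr[:, 0], edge_arr[:, 1]] = 1
    base_adj[edge_arr[:, 1], edge_arr[:, 0]] = 1
    observed = _internal_counts(edge_arr, member_idx, len(comm_ids))
    exceed = np.zeros(len(comm_ids), dtype=int)
    n_attempts = 10 * m
    for sample in range(n_null):
        rng = substream(seed, "null", sample)
        arr = edge_arr.copy()
        adj = base_adj.copy()
        idx1 = rng.integers(0, m, size=n_attempts)
        idx2 = rng.integers(0, m, size=n_attempts)
        flips = rng.random(n_attempts) < 0.5
        _swap_kernel(arr, adj, idx1, idx2, flips)
        counts = _internal_counts(arr, member_idx, len(comm_ids))
        exceed += counts >= observed
    pvals = (1 + exceed) / (n_null + 1)
    return {c: float(pvals[comm_idx[c]]) for c in comm_ids}
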