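"""Thresholded network graphs and modularity communities.

A connectivity matrix becomes a weighted graph by keeping only its
strongest positive entries — either a fixed edge count, a target
average degree (e.g. 20 directed / 10 undirected connections per node),
or a plain weight cutoff.  Communities are found by Louvain modularity
optimization; when a fixed community count is requested (to match an
ICA decomposition, say), the resolution parameter is bisected until the
partition has that many communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

from .types import ConnectivityMatrix

__all__ = [
    "NetworkGraph",
    "CommunityPartition",
    "threshold_graph",
    "detect_communities",
    "detect_communities_edge_search",
    "community_sizes",
    "filter_small",
    "export_layout",
]

logger = logging.getLogger(__name__)

THRESHOLD_RULES = ("top_n_edges", "avg_degree", "z_cutoff")


@dataclass
class NetworkGraph:
    """Weighted graph over atlas regions, positive weights only."""

    graph: nx.Graph | nx.DiGraph
    directed: bool
    threshold_rule: str
    threshold_value: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def is_fully_connected(self) -> bool:
        """Whether every node is reachable from every other (weakly, if directed)."""
        if self.n_nodes == 0:
            return False
        if self.directed:
            return nx.is_weakly_connected(self.graph)
        return nx.is_connected(self.graph)


@dataclass
class CommunityPartition:
    """Disjoint node partition with its modularity score."""

    assignment: dict[int, int]
    modularity: float
    n_communities: int
    target_reached: bool = True
    resolution: float = 1.0

    def as_sets(self) -> list[set[int]]:
        sets: dict[int, set[int]] = {}
        for node, comm in self.assignment.items():
            sets.setdefault(comm, set()).add(node)
        return [sets[c] for c in sorted(sets)]


def threshold_graph(
    matrix: ConnectivityMatrix, rule: str = "avg_degree", value: float = 20
) -> NetworkGraph:
    """Keep the strongest positive connections of a matrix as a graph.

    Rules: ``avg_degree`` keeps the N*d/2 strongest connections
    (directed entries or unique undirected pairs; a connection touches
    two nodes, so that yields average degree d); ``top_n_edges`` keeps
    exactly n; ``z_cutoff`` keeps every entry >= value.  Ties at the
    cut are broken by (weight desc, source id asc, target id asc).
    All region ids are kept as nodes, so weaker regions appear as
    isolated vertices rather than disappearing.
    """
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {rule!r}; use one of {THRESHOLD_RULES}")
    vals = matrix.values
    ids = matrix.region_ids
    n = matrix.n_regions
    if matrix.directed:
        src, dst = np.nonzero(~np.eye(n, dtype=bool))
    else:
        src, dst = np.triu_indices(n, k=1)
    w = vals[src, dst]
    pos = w > 0
    src, dst, w = src[pos], dst[pos], w[pos]
    order = np.lexsort((dst, src, -w))
    src, dst, w = src[order], dst[order], w[order]
    if rule == "z_cutoff":
        keep = w >= value
        src, dst, w = src[keep], dst[keep], w[keep]
    else:
        if rule == "avg_degree":
            # each connection touches two nodes, so N nodes at average
            # degree d carry N*d/2 connections (directed or not)
            n_want = int(round(n * value / 2.0))
        else:
            n_want = int(value)
        if n_want > w.size:
            logger.warning(
                "requested %d edges but only %d positive entries available; keeping all",
                n_want,
                w.size,
            )
            n_want = w.size
        src, dst, w = src[:n_want], dst[:n_want], w[:n_want]
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if matrix.directed else nx.Graph()
    g.add_nodes_from(int(i) for i in ids)
    g.add_weighted_edges_from(
        (int(ids[s]), int(ids[d]), float(wt)) for s, d, wt in zip(src, dst, w)
    )
    return NetworkGraph(
        graph=g, directed=matrix.directed, threshold_rule=rule, threshold_value=float(value)
    )


def _symmetrized(graph: NetworkGraph) -> nx.Graph:
    """Undirected view; reciprocal directed weights are summed."""
    if not graph.directed:
        return graph.graph
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    for u, v, w in graph.graph.edges(data="weight"):
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def _louvain(g: nx.Graph, resolution: float, seed: int) -> list[set[int]]:
    return nx_comm.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)


def detect_communities(
    graph: NetworkGraph,
    target_count: int | None = None,
    seed: int = 0,
    max_bisections: int = 50,
) -> CommunityPartition:
    """Louvain modularity communities, optionally at a fixed count.

    Directed graphs are symmetrized (reciprocal weights summed) first.
    If the natural partition does not have ``target_count`` communities,
    the Louvain resolution parameter is bisected toward the target; if
    the exact count is unreachable (e.g. more disconnected components
    than the target), the closest achievable partition is returned with
    ``target_reached=False`` and a warning.
    """
    g = _symmetrized(graph)
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("community detection needs a graph with at least one edge")

    def run(res: float) -> list[set[int]]:
        return _louvain(g, res, seed)

    resolution = 1.0
    comms = run(resolution)
    best = (abs(len(comms) - (target_count or len(comms))), resolution, comms)
    if target_count is not None and len(comms) != target_count:
        lo, hi = resolution, resolution
        lo_c, hi_c = comms, comms
        while len(lo_c) > target_count and lo > 1e-8:
            lo /= 2.0
            lo_c = run(lo)
        while len(hi_c) < target_count and hi < 1e8:
            hi *= 2.0
            hi_c = run(hi)
        for cand_res, cand in ((lo, lo_c), (hi, hi_c)):
            score = abs(len(cand) - target_count)
            if score < best[0]:
                best = (score, cand_res, cand)
        for _ in range(max_bisections):
            if best[0] == 0:
                break
            mid = 0.5 * (lo + hi)
            mid_c = run(mid)
            score = abs(len(mid_c) - target_count)
            if score < best[0]:
                best = (score, mid, mid_c)
            if len(mid_c) < target_count:
                lo = mid
            elif len(mid_c) > target_count:
                hi = mid
            else:
                break
        comms = best[2]
        resolution = best[1]
        if len(comms) != target_count:
            logger.warning(
                "could not reach %d communities; closest achievable was %d",
                target_count,
                len(comms),
            )
    q = nx_comm.modularity(g, comms, weight="weight")
    ordered = sorted(comms, key=lambda s: min(s))
    assignment = {int(node): ci for ci, nodes in enumerate(ordered) for node in nodes}
    return CommunityPartition(
        assignment=assignment,
        modularity=float(q),
        n_communities=len(comms),
        target_reached=(target_count is None or len(comms) == target_count),
        resolution=float(resolution),
    )


def detect_communities_edge_search(
    matrix: ConnectivityMatrix,
    target_count: int,
    seed: int = 0,
    n_min: int = 1,
    n_max: int | None = None,
    max_bisections: int = 40,
) -> tuple[CommunityPartition, NetworkGraph]:
    """Reach a community count by varying the kept edge count instead.

    Alternative to the resolution search: the matrix is re-thresholded
    at different top-n edge counts (fewer edges -> more communities)
    and the count is bisected until Louvain at resolution 1 yields
    ``target_count`` communities; the closest achievable partition is
    returned otherwise, together with the graph that produced it.
    """
    available = int((matrix.values > 0).sum()) if matrix.directed else int(
        (np.triu(matrix.values, k=1) > 0).sum()
    )
    if available == 0:
        raise ValueError("matrix has no positive entries to threshold")
    n_max = min(n_max or available, available)

    def run(n_edges: int):
        g = threshold_graph(matrix, rule="top_n_edges", value=n_edges)
        if g.n_edges == 0:
            return g, None
        return g, detect_communities(g, target_count=None, seed=seed)

    lo, hi = max(n_min, 1), n_max
    best: tuple[int, CommunityPartition, NetworkGraph] | None = None
    for _ in range(max_bisections):
        mid = (lo + hi) // 2
        g, part = run(mid)
        if part is not None:
            score = abs(part.n_communities - target_count)
            if best is None or score < best[0]:
                best = (score, part, g)
            if score == 0:
                break
        if part is None or part.n_communities > target_count:
            lo = mid + 1  # too sparse: add edges to merge communities
        else:
            hi = mid - 1
        if lo > hi:
            break
    if best is None:
        raise ValueError("no edge count produced a usable graph")
    if best[0] != 0:
        logger.warning(
            "edge search could not reach %d communities; closest was %d",
            target_count,
            best[1].n_communities,
        )
    return best[1], best[2]


def community_sizes(partition: CommunityPartition) -> dict[int, int]:
    """Node count per community id."""
    sizes: dict[int, int] = {}
    for comm in partition.assignment.values():
        sizes[comm] = sizes.get(comm, 0) + 1
    return dict(sorted(sizes.items()))


def filter_small(partition: CommunityPartition, min_nodes: int = 4) -> CommunityPartition:
    """Drop communities with fewer than ``min_nodes`` nodes."""
    sizes = community_sizes(partition)
    keep = {c for c, s in sizes.items() if s >= min_nodes}
    assignment = {n: c for n, c in partition.assignment.items() if c in keep}
    return CommunityPartition(
        assignment=assignment,
        modularity=partition.modularity,
        n_communities=len(keep),
        target_reached=partition.target_reached,
        resolution=partition.resolution,
    )


def export_layout(
    graph: NetworkGraph,
    partition: CommunityPartition | None = None,
    seed: int = 0,
    dim: int = 2,
) -> pd.DataFrame:
    """Seeded force-directed node coordinates for plotting.

    Returns a table with one row per node: node id, community (if a
    partition is given), and ``dim`` coordinate columns.  Deterministic
    given the seed.
    """
    g = _symmetrized(graph)
    if g.number_of_nodes() == 0:
        cols = ["node"] + [f"coord_{a}" for a in "xyz"[:dim]]
        return pd.DataFrame(columns=cols)
    pos = nx.spring_layout(g, weight="weight", seed=seed, dim=dim)
    rows = []
    for node in sorted(g.nodes):
        row: dict[str, float | int] = {"node": int(node)}
        if partition is not None:
            row["community"] = partition.assignment.get(int(node), -1)
        for axis, value in zip("xyz", pos[node]):
            row[f"coord_{axis}"] = float(value)
        rows.append(row)
    return pd.DataFrame(rows)
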