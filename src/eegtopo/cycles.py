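"""Node importance via cycle ratio on persistence-derived graphs.

The most persistent homology classes of a band's filtration pick out
thresholds of the correlation-distance matrix; the 1-skeleton of the
Vietoris-Rips complex at a class's birth value is the graph in which the
class demonstrably exists and is not yet filled.  On each such graph every
node is scored by its *cycle ratio*: for every node j that lies on at
least one cycle, consider the set S_j of minimum-edge-count cycles through
j; node i earns, from each j, the fraction of S_j's cycles that contain i.
Summing over j (including j = i) gives r_i.  Nodes on no cycle score 0;
any node on a cycle scores at least 1 (its own shortest cycles all contain
it).  Top-scoring nodes are tallied across graphs, segments and subjects.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections import Counter

import numpy as np

from .config import PipelineConfig
from .connectivity import DistanceMatrix, correlation_distance
from .homology import PersistenceDiagram, vr_persistence
from .preprocess import band_filter, segment_windows

logger = logging.getLogger(__name__)

__all__ = [
    "FiltrationSubgraph",
    "CycleRatioScores",
    "NodeTally",
    "top_persistent_classes",
    "extract_subgraph",
    "cycle_ratio",
    "tally_top_nodes",
    "run_cycle_analysis",
]


@dataclasses.dataclass
class FiltrationSubgraph:
    """1-skeleton of the VR complex at one class's threshold.

    ``nodes`` lists the non-isolated channels; ``edges`` the pairs with
    dissimilarity at or below ``threshold``.
    """

    nodes: list[int]
    edges: list[tuple[int, int]]
    source_pair: tuple[float, float, int]
    threshold: float

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


@dataclasses.dataclass
class CycleRatioScores:
    """Per-node cycle-ratio values and shortest-cycle lengths."""

    r: dict[int, float]
    shortest_cycle_length: dict[int, int | None]

    def ranked(self) -> list[int]:
        """Nodes by decreasing r, ties broken by node index."""
        return sorted(self.r, key=lambda v: (-self.r[v], v))


@dataclasses.dataclass
class NodeTally:
    """How often each node made a graph's top-k by cycle ratio."""

    counts: Counter
    n_graphs: int

    def top(self, k: int = 10) -> list[tuple[int, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def to_dataframe(self):
        import pandas as pd

        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["node_number", "times_recorded"])


def top_persistent_classes(
    pd_obj: PersistenceDiagram, k: int = 5, dims: tuple[int, ...] | None = None
) -> list[tuple[float, float, int]]:
    """The k finite pairs with the largest lifetimes.

    By default all dimensions are pooled; pass ``dims=(1,)`` to restrict to
    1-cycles.  Essential classes are excluded; ties broken by (smaller
    birth, lower dim) for determinism.  Fewer than k pairs are returned
    for small diagrams.
    """
    finite = pd_obj.finite_pairs
    if dims is not None:
        finite = finite[np.isin(finite[:, 2], dims)]
    ranked = sorted(
        (tuple(row) for row in finite),
        key=lambda p: (-(p[1] - p[0]), p[0], p[2]),
    )
    return [(float(b), float(d), int(q)) for b, d, q in ranked[:k]]


def extract_subgraph(
    D: DistanceMatrix | np.ndarray, pair, at: str = "birth"
) -> FiltrationSubgraph:
    """1-skeleton at the class's birth (default) or death threshold.

    At birth a 1-cycle class provably exists and is not yet filled, which
    makes birth the canonical threshold; ``at="death"`` is offered for the
    alternative reading.  Isolated nodes are dropped.
    """
    birth, death = float(pair[0]), float(pair[1])
    if np.isinf(death):
        raise ValueError("essential classes have no finite lifetime to localize")
    if at not in ("birth", "death"):
        raise ValueError("at must be 'birth' or 'death'")
    threshold = birth if at == "birth" else death
    M = D.D if hasattr(D, "D") else np.asarray(D, dtype=float)
    n = M.shape[0]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if M[i, j] <= threshold
    ]
    nodes = sorted({v for e in edges for v in e})
    return FiltrationSubgraph(
        nodes=nodes,
        edges=edges,
        source_pair=(birth, death, int(pair[2])),
        threshold=threshold,
    )


def _bfs_dist(adj: dict[int, set[int]], start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _shortest_cycles_through(
    adj: dict[int, set[int]], j: int, cap: int
) -> tuple[int | None, list[frozenset[int]]]:
    """All minimum-length simple cycles through node j.

    Iterative deepening DFS from j with a BFS-distance pruning bound; each
    cycle is found once by requiring the second node's index below the last
    node's.  Returns (cycle length, cycles as node frozensets paired with
    their edge sets) — cycles are kept as edge frozensets to distinguish
    cycles sharing a node set.
    """
    dist = _bfs_dist(adj, j)
    reachable = [v for v in adj[j] if v in dist]
    if not reachable:
        return None, []
    n_reach = len(dist)
    for length in range(3, n_reach + 1):
        cycles: list[frozenset] = []
        # DFS over simple paths j -> ... of exactly `length` nodes closing at j
        stack: list[tuple[int, list[int], set[int]]] = [(j, [j], {j})]
        while stack:
            u, path, seen = stack.pop()
            k = len(path)
            if k == length:
                if j in adj[u] and path[1] < path[-1]:
                    cycles.append(
                        frozenset(
                            frozenset(e)
                            for e in zip(path, path[1:] + [j])
                        )
                    )
                    if len(cycles) >= cap:
                        warnings.warn(
                            f"cycle enumeration capped at {cap} cycles for node {j}",
                            stacklevel=2,
                        )
                        stack.clear()
                continue
            for v in adj[u]:
                if v in seen:
                    continue
                # must still be able to return to j within the budget
                if dist.get(v, np.inf) > length - k:
                    continue
                stack.append((v, path + [v], seen | {v}))
        if cycles:
            return length, cycles
    return None, []


def cycle_ratio(g: FiltrationSubgraph, cap: int = 10_000) -> CycleRatioScores:
    """Cycle-ratio score of every node in the graph."""
    import networkx as nx

    adj = g.adjacency()
    r: dict[int, float] = {v: 0.0 for v in g.nodes}
    shortest: dict[int, int | None] = {v: None for v in g.nodes}
    # cycles live inside biconnected components of >= 3 nodes; everything
    # else (bridges, leaves) can be skipped outright
    G = nx.Graph(g.edges)
    G.add_nodes_from(g.nodes)
    cyclic = set().union(*(c for c in nx.biconnected_components(G) if len(c) >= 3), set())
    for j in g.nodes:
        if j not in cyclic:
            continue
        length, cycles = _shortest_cycles_through(adj, j, cap)
        shortest[j] = length
        if not cycles:
            continue
        share = 1.0 / len(cycles)
        for cyc in cycles:
            members = {v for edge in cyc for v in edge}
            for v in members:
                r[v] += share
    return CycleRatioScores(r=r, shortest_cycle_length=shortest)


def tally_top_nodes(scores_per_graph: list[CycleRatioScores], top_k: int = 10) -> NodeTally:
    """Count, per node, in how many graphs it ranked in the top_k by r."""
    if not scores_per_graph:
        raise ValueError("need at least one scored graph")
    counts: Counter = Counter()
    for scores in scores_per_graph:
        for v in scores.ranked()[:top_k]:
            counts[v] += 1
    return NodeTally(counts=counts, n_graphs=len(scores_per_graph))


def run_cycle_analysis(
    recordings,
    config: PipelineConfig | None = None,
    segment_length: float = 40.0,
    top_classes: int = 5,
    top_k: int = 10,
    dims: tuple[int, ...] = (1,),
) -> dict[str, NodeTally]:
    """Full cycle-ratio tally per frequency band over a cohort.

    For every recording, band and non-overlapping segment: correlation
    distance -> VR persistence -> the ``top_classes`` most persistent
    classes -> birth-threshold subgraphs -> cycle-ratio scores; the top_k
    nodes of every graph feed the band's tally.  The per-subject graph
    count (bands x segments x classes) is logged explicitly.

    ``dims`` defaults to the 1-dimensional classes: dim-0 classes are all
    born at filtration value 0, so their birth-threshold subgraphs are
    empty by construction and would contribute nothing.
    """
    config = config or PipelineConfig()
    tallies: dict[str, NodeTally] = {}
    for band_name, band in config.bands.items():
        scored: list[CycleRatioScores] = []
        graphs_per_subject: list[int] = []
        for rec in recordings:
            n_graphs = 0
            sig = band_filter(rec, band, band_name)
            for segment in segment_windows(sig, segment_length):
                dm = correlation_distance(segment)
                diagram = vr_persistence(dm, max_dim=1)
                for pair in top_persistent_classes(diagram, k=top_classes, dims=dims):
                    sub = extract_subgraph(dm, pair)
                    if not sub.nodes:
                        continue
                    scored.append(cycle_ratio(sub))
                    n_graphs += 1
            graphs_per_subject.append(n_graphs)
        logger.info(
            "band %s: %d graphs total (per subject: %s)",
            band_name,
            len(scored),
            graphs_per_subject,
        )
        if scored:
            tallies[band_name] = tally_top_nodes(scored, top_k=top_k)
    return tallies
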