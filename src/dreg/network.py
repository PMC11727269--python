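"""Interactome analysis of a candidate gene set.

Builds a deduplicated undirected protein-protein interaction graph from edge
lists, computes the gene-set-induced subgraph and its centralities, tests the
observed induced edge count against a node-matched permutation null
(empirical p = (exceedances + 1) / (B + 1)), compares degree and betweenness
of members against background genes with the Wilcoxon rank-sum test, calls
hub genes (within-set degree >= 20 by default) and detects cohesive modules
with a greedy cohesiveness-growth procedure in the style of ClusterONE:
f(V) = w_in / (w_in + w_bound + penalty * |V|), grown from high-degree seeds,
overlapping results merged at omega >= 0.8 and scored by a one-sided
Mann-Whitney test of internal versus boundary node degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "betweenness_dict",
    "SubnetworkStats",
    "PermutationResult",
    "Module",
    "build_interactome",
    "induced_stats",
    "connectivity_permutation_test",
    "centrality_comparison",
    "find_hubs",
    "detect_modules",
]


@dataclass
class SubnetworkStats:
    members: list[str]  # gene-set members present in the graph
    n_induced_edges: int
    per_node: pd.DataFrame  # within_degree, degree, betweenness

    def __post_init__(self) -> None:
        m = len(self.members)
        assert self.n_induced_edges <= m * (m - 1) // 2


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    pvalue: float
    seed: int
    n_permutations: int
    tail: str = "upper"


@dataclass
class Module:
    members: frozenset[str]
    cohesiveness: float
    pvalue: float
    boundary_size: int


# --------------------------------------------------------------------------

def betweenness_dict(graph: nx.Graph) -> dict:
    """Unnormalized betweenness (unordered pairs, endpoints excluded).

    Uses igraph's C implementation when available (identical counting
    convention for undirected graphs); falls back to networkx.
    """
    try:
        import igraph
    except ImportError:  # pragma: no cover - igraph is a declared dependency
        return nx.betweenness_centrality(graph, normalized=False)
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes), edges=[(index[a], index[b]) for a, b in graph.edges]
    )
    return dict(zip(nodes, g.betweenness(directed=False)))


def build_interactome(edge_files: list[str | Path]) -> nx.Graph:
    """Union of 2-3-column edge TSVs into a simple undirected graph.

    Direction-insensitive deduplication; self-loops dropped (counted in
    ``graph.graph['n_self_loops']``); per-edge source provenance retained as
    the ``sources`` edge attribute.
    """
    graph = nx.Graph()
    n_self = 0
    for path in edge_files:
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
                a, b = fields[0], fields[1]
                src = fields[2] if len(fields) > 2 else path.name
                if a == b:
                    n_self += 1
                    continue
                if graph.has_edge(a, b):
                    graph.edges[a, b]["sources"].add(src)
                else:
                    graph.add_edge(a, b, sources={src})
    graph.graph["n_self_loops"] = n_self
    logger.info(
        "interactome: %d nodes, %d edges (%d self-loops dropped)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        n_self,
    )
    return graph


def induced_count(graph: nx.Graph, members: set[str]) -> int:
    """Number of edges of the subgraph induced by ``members``."""
    return sum(1 for a, b in graph.edges(members) if a in members and b in members)


def induced_stats(
    graph: nx.Graph,
    gene_set: set[str] | list[str],
    betweenness: dict | None = None,
) -> SubnetworkStats:
    """Induced-subgraph statistics for a gene set.

    Betweenness is computed on the full graph (unweighted shortest-path
    counting over unordered pairs, endpoints excluded); a precomputed
    betweenness dict may be passed to avoid recomputation.
    """
    if not gene_set:
        raise ValueError("gene_set is empty")
    members = sorted(set(gene_set) & set(graph.nodes))
    sub = graph.subgraph(members)
    if betweenness is None:
        betweenness = betweenness_dict(graph)
    per_node = pd.DataFrame(
        {
            "within_degree": [sub.degree(g) for g in members],
            "degree": [graph.degree(g) for g in members],
            "betweenness": [betweenness[g] for g in members],
        },
        index=members,
    )
    return SubnetworkStats(members, sub.number_of_edges(), per_node)


def connectivity_permutation_test(
    graph: nx.Graph,
    gene_set: set[str] | list[str],
    n_permutations: int = 1000,
    seed: int = 0,
    tail: str = "upper",
) -> PermutationResult:
    """Node-matched permutation test of induced edge count.

    Null draws are uniform samples of graph nodes of the same size as the
    in-graph member set; the statistic is the induced edge count and the
    empirical p uses the add-one estimator (r + 1) / (B + 1).
    """
    nodes = np.array(sorted(graph.nodes))
    if len(set(gene_set)) > len(nodes):
        raise ValueError("gene set larger than the graph")
    members = set(gene_set) & set(graph.nodes)
    k = len(members)
    if k < 2:
        raise ValueError("need at least two gene-set members present in the graph")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes}

    def count(sel: set[str]) -> int:
        return sum(len(adj[n] & sel) for n in sel) // 2

    observed = count(members)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        draw = set(rng.choice(nodes, size=k, replace=False))
        null[b] = count(draw)
    if tail == "upper":
        r = int((null >= observed).sum())
    elif tail == "lower":
        r = int((null <= observed).sum())
    elif tail == "two-sided":
        center = np.median(null)
        r = int((np.abs(null - center) >= abs(observed - center)).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (r + 1) / (n_permutations + 1)
    return PermutationResult(observed, null, p, seed, n_permutations, tail)


def centrality_comparison(
    graph: nx.Graph,
    gene_set: set[str] | list[str],
    betweenness: dict | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of members vs background genes.

    Compares whole-graph degree and betweenness centrality; returns one row
    per metric with group medians, the Mann-Whitney U statistic and p.
    """
    members = sorted(set(gene_set) & set(graph.nodes))
    background = sorted(set(graph.nodes) - set(members))
    if not members or not background:
        raise ValueError("both member and background groups must be nonempty")
    if betweenness is None:
        betweenness = betweenness_dict(graph)
    rows = []
    for metric, value in (
        ("degree", dict(graph.degree)),
        ("betweenness", betweenness),
    ):
        x = np.array([value[g] for g in members], dtype=float)
        y = np.array([value[g] for g in background], dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            (
                metric,
                float(np.median(x)),
                float(np.median(y)),
                float(res.statistic),
                float(res.pvalue),
            )
        )
    return pd.DataFrame(
        rows, columns=["metric", "median_members", "median_background", "U", "pvalue"]
    ).set_index("metric")


def find_hubs(stats_: SubnetworkStats, k_min: int = 20) -> list[str]:
    """Members with within-set degree >= k_min, by degree then gene ID."""
    t = stats_.per_node
    hubs = t.index[t["within_degree"] >= k_min]
    return sorted(hubs, key=lambda g: (-t.loc[g, "within_degree"], g))


# --------------------------------------------------------------------------
# Greedy cohesiveness module detection
# --------------------------------------------------------------------------

def _cohesiveness(
    members: set[str], adj: dict[str, set[str]], penalty: float
) -> float:
    w_in = sum(len(adj[n] & members) for n in members) / 2.0
    w_bound = sum(len(adj[n] - members) for n in members)
    den = w_in + w_bound + penalty * len(members)
    return w_in / den if den > 0 else 0.0


def detect_modules(
    graph: nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    overlap_merge: float = 0.8,
    seed: int = 0,
) -> list[Module]:
    """Greedy cohesiveness-growth module detection (ClusterONE scheme).

    Seeds are nodes in decreasing degree order not yet covered by a module;
    from each seed, boundary nodes are greedily added (or members removed)
    while f(V) = w_in / (w_in + w_bound + penalty*|V|) increases.  Grown sets
    with overlap omega(A,B) = |A∩B|^2 / (|A||B|) >= overlap_merge are merged;
    modules smaller than min_size are discarded.  Each module's p-value is a
    one-sided Mann-Whitney test of member vs boundary whole-graph degrees.
    Deterministic: ties in the seed order are broken by node ID.
    """
    if graph.number_of_nodes() == 0:
        return []
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes}
    order = sorted(graph.nodes, key=lambda n: (-graph.degree(n), str(n)))
    covered: set[str] = set()
    grown: list[set[str]] = []
    for s in order:
        if s in covered:
            continue
        members = {s}
        score = _cohesiveness(members, adj, penalty)
        improved = True
        while improved:
            improved = False
            boundary = set().union(*(adj[n] for n in members)) - members
            best_delta, best_action = 0.0, None
            for cand in sorted(boundary):
                new = _cohesiveness(members | {cand}, adj, penalty)
                if new - score > best_delta + 1e-12:
                    best_delta, best_action = new - score, ("add", cand)
            if len(members) > 1:
                for cand in sorted(members):
                    new = _cohesiveness(members - {cand}, adj, penalty)
                    if new - score > best_delta + 1e-12:
                        best_delta, best_action = new - score, ("remove", cand)
            if best_action is not None:
                kind, node = best_action
                members = members | {node} if kind == "add" else members - {node}
                score += best_delta
                improved = True
        grown.append(members)
        covered |= members

    # merge highly overlapping candidates
    merged = True
    while merged:
        merged = False
        for i in range(len(grown)):
            for j in range(i + 1, len(grown)):
                a, b = grown[i], grown[j]
                inter = len(a & b)
                if inter and inter * inter / (len(a) * len(b)) >= overlap_merge:
                    grown[i] = a | b
                    del grown[j]
                    merged = True
                    break
            if merged:
                break

    modules = []
    for members in grown:
        if len(members) < min_size:
            continue
        boundary = set().union(*(adj[n] for n in members)) - members
        deg_in = np.array([graph.degree(n) for n in members], dtype=float)
        if boundary:
            deg_out = np.array([graph.degree(n) for n in boundary], dtype=float)
            p = float(
                stats.mannwhitneyu(deg_in, deg_out, alternative="greater").pvalue
            )
        else:
            p = 1.0 / (len(members) + 1.0)  # isolated component: no boundary
        modules.append(
            Module(
                frozenset(members),
                _cohesiveness(members, adj, penalty),
                p,
                len(boundary),
            )
        )
    modules.sort(key=lambda m: (-m.cohesiveness, sorted(m.members)))
    return modules
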