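"""Network indicator panel for weighted undirected graphs.

Computes the nine standard descriptors used to characterise each
entity-specific network: node and edge counts, average (weighted)
degree, average shortest-path length, graph density, modularity and
community count of a greedy modularity partition, and the average
clustering coefficient.

Conventions:

* average path length is the mean unweighted shortest-path distance over
  all *connected* ordered node pairs — disconnected pairs are excluded
  rather than imputed, which keeps the value finite on fragmented
  subnetworks (isolated seed entities are common);
* community detection is deterministic greedy modularity maximisation
  (Clauset–Newman–Moore) on edge weights; ``seed`` is accepted for
  interface stability but the default algorithm ignores it;
* nodes of degree < 2 contribute a local clustering coefficient of 0
  (they are averaged in, not excluded).

Values are kept at full precision; round only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import networkx as nx
from networkx.algorithms import community as nx_community

__all__ = [
    "NetworkStats",
    "degree_stats",
    "density",
    "avg_path_length",
    "avg_clustering",
    "communities_and_modularity",
    "summarize",
]


@dataclass(frozen=True)
class NetworkStats:
    """The indicator panel for one network."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_weighted_degree: float
    avg_path_length: float  # NaN when no pair is connected
    density: float
    modularity: float
    n_communities: int
    avg_clustering: float

    def as_dict(self) -> dict:
        return asdict(self)


def degree_stats(g: nx.Graph) -> tuple[float, float]:
    """(average degree, average weighted degree) = (2E/N, 2·Σw/N)."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("degree_stats requires a non-empty graph")
    avg_deg = 2.0 * g.number_of_edges() / n
    total_weight = sum(data.get("weight", 1) for _u, _v, data in g.edges(data=True))
    return avg_deg, 2.0 * total_weight / n


def density(g: nx.Graph) -> float:
    """Graph density 2E / (N (N−1)); requires at least two nodes."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def avg_path_length(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over connected ordered pairs.

    Pairs in different components are excluded.  If no two nodes are
    connected the quantity is undefined and NaN is returned.
    """
    total = 0
    pairs = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                pairs += 1
    if pairs == 0:
        return math.nan
    return total / pairs


def avg_clustering(g: nx.Graph) -> float:
    """Mean unweighted local clustering coefficient; degree-<2 nodes count 0.

    Exactly zero on triangle-free graphs.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("avg_clustering requires a non-empty graph")
    return nx.average_clustering(g, weight=None, count_zeros=True)


def communities_and_modularity(
    g: nx.Graph, seed: int = 0
) -> tuple[list[set], float]:
    """Deterministic greedy modularity partition and its weighted Q.

    Uses Clauset–Newman–Moore greedy agglomeration with edge weights.
    An edgeless graph yields the singleton partition with Q = 0.  The
    ``seed`` argument is reserved for randomized variants; the greedy
    algorithm is deterministic and does not consume it.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("community detection requires a non-empty graph")
    if g.number_of_edges() == 0:
        return [{n} for n in g.nodes], 0.0
    communities = [
        set(c)
        for c in nx_community.greedy_modularity_communities(g, weight="weight")
    ]
    q = nx_community.modularity(g, communities, weight="weight")
    return communities, q


def summarize(g: nx.Graph, seed: int = 0) -> NetworkStats:
    """Compute the full indicator panel for one graph (N ≥ 2)."""
    if g.number_of_nodes() < 2:
        raise ValueError("summarize requires at least 2 nodes")
    avg_deg, avg_wdeg = degree_stats(g)
    communities, q = communities_and_modularity(g, seed=seed)
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        avg_degree=avg_deg,
        avg_weighted_degree=avg_wdeg,
        avg_path_length=avg_path_length(g),
        density=density(g),
        modularity=q,
        n_communities=len(communities),
        avg_clustering=avg_clustering(g),
    )
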