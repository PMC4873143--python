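"""Entity ranking on the paper-entity graph.

Two complementary importance measures are computed on the full
heterogeneous graph (papers participate in the score flow) and then
filtered to entity nodes:

* **PageRank** — the stationary distribution of a random walk with
  teleportation; high scores mark entities that many papers (and,
  transitively, well-connected papers) mention.  Computed by power
  iteration with uniform teleportation, each undirected edge treated as
  a pair of directed links; dangling (isolated) nodes spread their mass
  uniformly.
* **Betweenness centrality** — the number of shortest paths between
  node pairs passing through a node (unnormalized, each unordered pair
  counted once, unweighted paths); high scores mark entities bridging
  otherwise separate parts of the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from litnet.corpus_io import EntityType
from litnet.networks import Entity, is_entity_node

logger = logging.getLogger(__name__)

__all__ = ["EntityScore", "PageRankScores", "pagerank", "betweenness", "score_entities", "top_entities"]


class PageRankScores(dict):
    """node → PageRank mass; carries convergence metadata."""

    converged: bool = True
    n_iter: int = 0


def pagerank(
    g: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> PageRankScores:
    """PageRank by power iteration on an undirected graph.

    Scores sum to 1 on any non-empty graph, including disconnected ones
    (teleportation redistributes dangling mass).  Iteration stops when
    the L1 change drops below ``tol``; if ``max_iter`` is reached first
    the result is still returned with ``converged`` False and a logged
    warning.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("pagerank requires a non-empty graph")
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    deg = np.array([g.degree(v) for v in nodes], dtype=float)
    dangling = deg == 0

    # sparse adjacency walk: x'_v = (1-d)/n + d * sum_{u ~ v} x_u / deg_u
    neighbors = [np.fromiter((index[u] for u in g.neighbors(v)), dtype=np.int64) for v in nodes]

    x = np.full(n, 1.0 / n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        contrib = np.where(dangling, 0.0, x / np.maximum(deg, 1.0))
        dangling_mass = x[dangling].sum()
        x_new = np.empty(n)
        for i in range(n):
            x_new[i] = contrib[neighbors[i]].sum()
        x_new = (1.0 - damping) / n + damping * (x_new + dangling_mass / n)
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        logger.warning("pagerank did not converge in %d iterations", max_iter)
    result = PageRankScores(zip(nodes, x.tolist()))
    result.converged = converged
    result.n_iter = iterations
    return result


def betweenness(g: nx.Graph) -> dict[Hashable, float]:
    """Exact unnormalized betweenness centrality (Brandes' algorithm).

    Unweighted shortest paths; each unordered pair counted once; pairs
    in different components contribute zero.
    """
    return nx.betweenness_centrality(g, normalized=False, weight=None)


@dataclass(frozen=True)
class EntityScore:
    entity: Entity
    pagerank: float
    betweenness: float
    rank_pr: int
    rank_bw: int


def score_entities(
    paper_entity: nx.Graph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[EntityScore]:
    """Score every entity node of the paper-entity graph.

    Both measures are computed over the full heterogeneous graph; paper
    nodes contribute to score flow but receive no ranks.  Ranks are 1-based
    positions under (score desc, name asc, type asc) ordering, assigned
    per measure across all entity types.
    """
    pr = pagerank(paper_entity, damping=damping, tol=tol, max_iter=max_iter)
    bw = betweenness(paper_entity)
    entities = [n for n in paper_entity.nodes if is_entity_node(paper_entity, n)]

    def ranks(scores: Mapping) -> dict[Entity, int]:
        ordered = sorted(
            entities, key=lambda e: (-scores[e], e.name, e.entity_type.value)
        )
        return {e: i + 1 for i, e in enumerate(ordered)}

    rank_pr = ranks(pr)
    rank_bw = ranks(bw)
    return [
        EntityScore(
            entity=e,
            pagerank=pr[e],
            betweenness=bw[e],
            rank_pr=rank_pr[e],
            rank_bw=rank_bw[e],
        )
        for e in sorted(entities, key=lambda e: rank_pr[e])
    ]


def top_entities(
    scores: Sequence[EntityScore],
    entity_type: EntityType,
    k: int,
    measure: str = "pagerank",
) -> list[EntityScore]:
    """The k best entities of one type under one measure.

    Ties break by (score desc, canonical name asc).  If fewer than k
    entities of the type exist, all are returned with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if measure not in ("pagerank", "betweenness"):
        raise ValueError(f"unknown measure {measure!r}")
    pool = [s for s in scores if s.entity.entity_type == entity_type]
    key = (lambda s: (-s.pagerank, s.entity.name)) if measure == "pagerank" else (
        lambda s: (-s.betweenness, s.entity.name)
    )
    pool.sort(key=key)
    if len(pool) < k:
        logger.warning(
            "only %d %s entities available (k=%d)", len(pool), entity_type.value, k
        )
    return pool[:k]
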