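"""Macro-level graphs: paper-entity bipartite and entity co-occurrence.

Both graphs are :class:`networkx.Graph` objects.  Paper nodes are plain
``doc_id`` strings tagged ``kind="paper"``; entity nodes are
:class:`Entity` named tuples ``(name, entity_type)`` tagged
``kind="entity"``, so a string occurring as both a drug and a gene
yields two distinct nodes.

The co-occurrence graph is the one-mode weighted projection of the
bipartite graph onto entities: the weight of edge (i, j) counts the
papers adjacent to both i and j.  Weights count *papers*, not mention
pairs, which follows from document-level deduplication upstream.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx

from litnet.corpus_io import EntityType, RelationRecord

__all__ = [
    "Entity",
    "build_paper_entity_graph",
    "build_cooccurrence_graph",
    "is_paper_node",
    "is_entity_node",
    "write_edgelist_tsv",
    "write_graphml",
]


class Entity(NamedTuple):
    """An entity node: canonical name plus its type."""

    name: str
    entity_type: EntityType

    def __str__(self) -> str:  # used for GraphML/TSV export labels
        return f"{self.name} [{self.entity_type.value}]"


def is_paper_node(g: nx.Graph, node) -> bool:
    return g.nodes[node].get("kind") == "paper"


def is_entity_node(g: nx.Graph, node) -> bool:
    return g.nodes[node].get("kind") == "entity"


def build_paper_entity_graph(records: Iterable[RelationRecord]) -> nx.Graph:
    """Build the heterogeneous unweighted paper-entity bipartite graph.

    One edge per distinct (doc, entity) pair; duplicated input rows are
    harmless.  Node sets are exactly the documents and entities present
    in ``records``; an empty input yields an empty graph.
    """
    g = nx.Graph()
    for rec in records:
        entity = Entity(rec.entity_name, rec.entity_type)
        g.add_node(rec.doc_id, kind="paper")
        g.add_node(entity, kind="entity", entity_type=rec.entity_type.value)
        g.add_edge(rec.doc_id, entity)
    return g


def build_cooccurrence_graph(paper_entity: nx.Graph) -> nx.Graph:
    """Project the bipartite graph onto entities with document co-counts.

    For every unordered entity pair (i, j), the edge weight is the
    number of papers adjacent to both; zero-weight pairs are absent.
    Every entity node of the input appears in the output (possibly
    isolated), preserving the heterogeneous node set.
    """
    cooc = nx.Graph()
    for node, data in paper_entity.nodes(data=True):
        if data.get("kind") == "entity":
            cooc.add_node(node, **data)
    for node, data in paper_entity.nodes(data=True):
        if data.get("kind") != "paper":
            continue
        entities = sorted(
            (nbr for nbr in paper_entity.neighbors(node)),
            key=lambda e: (e.name, e.entity_type.value),
        )
        for a, b in combinations(entities, 2):
            if cooc.has_edge(a, b):
                cooc[a][b]["weight"] += 1
            else:
                cooc.add_edge(a, b, weight=1)
    return cooc


def write_edgelist_tsv(g: nx.Graph, path: str | Path) -> None:
    """Export a graph as a weighted edge-list TSV (source, target, weight)."""
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data.get("weight", 1)))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in sorted(rows):
            fh.write(f"{a}\t{b}\t{w}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """Export for external visualization; tuple nodes become labels.

    GraphML supports scalar attributes only, so non-scalar graph-level
    metadata (e.g. seed lists) is serialized to strings.
    """
    relabeled = nx.relabel_nodes(g, {n: str(n) for n in g.nodes}, copy=True)
    for key, value in list(relabeled.graph.items()):
        if not isinstance(value, (str, int, float, bool)):
            relabeled.graph[key] = str(value)
    nx.write_graphml(relabeled, str(path))
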