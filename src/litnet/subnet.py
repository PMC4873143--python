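"""Meso-level entity-specific networks and salient pair extraction.

From the co-occurrence graph and a seed set (the top-ranked entities of
one type under one measure), an *entity-specific network* collects the
seeds plus, for each seed, its most strongly co-occurring same-type
neighbours, with the parent graph's co-occurrence weights preserved
exactly.  With three entity types and two ranking measures this yields
the six homogeneous subnetworks characterised downstream.

Salient pairs are the heaviest edges of each subnetwork, reported in
three co-occurrence bins (≥ 1000, 100–999, < 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

import networkx as nx

from litnet.corpus_io import EntityType
from litnet.networks import Entity

__all__ = [
    "EntityPair",
    "select_neighbors",
    "build_entity_network",
    "top_pairs",
    "weight_bin",
    "BIN_LABELS",
]

DEFAULT_BIN_THRESHOLDS = (100, 1000)


def bin_labels(thresholds: tuple[int, int] = DEFAULT_BIN_THRESHOLDS) -> tuple[str, str, str]:
    """Reporting labels for the three weight bins, heaviest first."""
    lo, hi = thresholds
    return (f">={hi}", f"{lo}-{hi - 1}", f"<{lo}")


BIN_LABELS = bin_labels()


def weight_bin(
    weight: int, thresholds: tuple[int, int] = DEFAULT_BIN_THRESHOLDS
) -> str:
    """Assign a co-occurrence count to its reporting bin.

    With the default thresholds the three bins partition the positive
    integers into ``>=1000``, ``100-999`` and ``<100``.
    """
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("bin thresholds must be strictly increasing positives")
    if weight < 1:
        raise ValueError("co-occurrence weights are positive integers")
    labels = bin_labels(thresholds)
    if weight >= hi:
        return labels[0]
    if weight >= lo:
        return labels[1]
    return labels[2]


@dataclass(frozen=True)
class EntityPair:
    a: Entity
    b: Entity
    weight: int
    bin: str

    def __post_init__(self) -> None:
        if self.a.name > self.b.name:
            raise ValueError("pair must be ordered (a <= b by name)")
        if self.bin in BIN_LABELS and weight_bin(self.weight) != self.bin:
            raise ValueError("bin inconsistent with weight")


def select_neighbors(
    cooc: nx.Graph,
    seeds: Set[Entity],
    entity_type: EntityType,
    per_seed: int = 5,
    min_weight: int = 2,
) -> set[Entity]:
    """Same-type entities that highly co-occur with the seeds.

    For each seed, its same-type neighbours with weight ≥ ``min_weight``
    are sorted by (weight desc, name asc) and the top ``per_seed`` kept;
    the union over seeds, minus the seeds themselves, is returned.
    """
    if any(s.entity_type != entity_type for s in seeds):
        raise ValueError("all seeds must be of the requested entity type")
    selected: set[Entity] = set()
    for seed in seeds:
        if seed not in cooc:
            continue
        candidates = [
            (nbr, cooc[seed][nbr]["weight"])
            for nbr in cooc.neighbors(seed)
            if isinstance(nbr, Entity)
            and nbr.entity_type == entity_type
            and cooc[seed][nbr]["weight"] >= min_weight
        ]
        candidates.sort(key=lambda item: (-item[1], item[0].name))
        selected.update(nbr for nbr, _w in candidates[:per_seed])
    return selected - set(seeds)


def build_entity_network(
    cooc: nx.Graph,
    seeds: Set[Entity],
    entity_type: EntityType,
    per_seed: int = 5,
    min_weight: int = 2,
    measure: str = "pagerank",
) -> nx.Graph:
    """Build one homogeneous entity-specific network.

    Nodes are the seeds plus their selected neighbours; edges are all
    parent-graph edges between those nodes of the requested type, with
    weights copied exactly.  Isolated seeds are retained, so the node
    count reflects the selection rather than connectivity.  Graph-level
    metadata (type, measure, parameters, seed set) is stored on
    ``graph.graph``.
    """
    neighbors = select_neighbors(
        cooc, seeds, entity_type, per_seed=per_seed, min_weight=min_weight
    )
    nodes = set(seeds) | neighbors
    net = nx.Graph(
        entity_type=entity_type.value,
        measure=measure,
        per_seed=per_seed,
        min_weight=min_weight,
        seeds=sorted(s.name for s in seeds),
    )
    for node in nodes:
        net.add_node(node, kind="entity", entity_type=entity_type.value,
                     is_seed=node in seeds)
    for u, v, data in cooc.edges(data=True):
        if u in nodes and v in nodes:
            net.add_edge(u, v, weight=data["weight"])
    return net


def top_pairs(
    net: nx.Graph,
    n_per_bin: int = 5,
    thresholds: tuple[int, int] = DEFAULT_BIN_THRESHOLDS,
) -> list[EntityPair]:
    """The heaviest co-occurring pairs of a subnetwork, per weight bin.

    Edges are assigned to the three bins by weight; within each bin they
    are sorted by (weight desc, pair-name asc) and the top ``n_per_bin``
    returned.  Bins with fewer qualifying pairs return what exists.
    Output is ordered heaviest bin first.
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    labels = bin_labels(thresholds)
    binned: dict[str, list[EntityPair]] = {label: [] for label in labels}
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v), key=lambda e: e.name)
        w = int(data["weight"])
        label = weight_bin(w, thresholds)
        binned[label].append(EntityPair(a=a, b=b, weight=w, bin=label))
    out: list[EntityPair] = []
    for label in labels:
        pairs = sorted(binned[label], key=lambda p: (-p.weight, p.a.name, p.b.name))
        out.extend(pairs[:n_per_bin])
    return out


def write_pairs_tsv(pairs: Iterable[EntityPair], path) -> None:
    """Pair report TSV: (bin, rank within bin, entity_a, entity_b, weight)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("bin\trank\tentity_a\tentity_b\tweight\n")
        rank = 0
        current = None
        for p in pairs:
            rank = rank + 1 if p.bin == current else 1
            current = p.bin
            fh.write(f"{p.bin}\t{rank}\t{p.a.name}\t{p.b.name}\t{p.weight}\n")
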