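"""Corpus input/output and synthetic corpus generation.

Reads PubMed-style XML (the ``MedlineCitation`` dialect: PMID,
ArticleTitle, AbstractText) into :class:`Document` records, reads and
writes tab-separated paper-entity relation tables, and generates
synthetic corpora with planted entities whose document frequencies,
community structure and co-occurrence counts are known exactly.

The synthetic generator is first-class: it plants entity surface forms
inside filler text drawn from a fixed, dictionary-free word list, so an
extractor running over the generated abstracts must recover exactly the
planted (document, entity) incidences — nothing more, nothing less.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import BinaryIO, Iterable, Sequence

import numpy as np
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "EntityType",
    "Document",
    "RelationRecord",
    "SyntheticCorpusConfig",
    "SyntheticGroundTruth",
    "parse_pubmed_xml",
    "write_pubmed_xml",
    "read_relation_table",
    "write_relation_table",
    "generate_synthetic_corpus",
]


class EntityType(str, Enum):
    """The three biomedical entity classes tracked by the pipeline."""

    DISEASE = "disease"
    DRUG = "drug"
    GENE = "gene"

    @classmethod
    def parse(cls, token: str) -> "EntityType":
        """Map a type token to the enum, case-insensitively."""
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown entity type {token!r}") from None


@dataclass(frozen=True)
class Document:
    """One paper: a PMID-like identifier plus title and abstract text."""

    doc_id: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        """Title and abstract joined, the region scanned for entities."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True, order=True)
class RelationRecord:
    """A document-level paper→entity incidence."""

    doc_id: str
    entity_name: str
    entity_type: EntityType


# ---------------------------------------------------------------------------
# PubMed-style XML
# ---------------------------------------------------------------------------


def parse_pubmed_xml(source: str | Path | BinaryIO | bytes) -> list[Document]:
    """Parse MedlineCitation-dialect XML into a list of :class:`Document`.

    One document is produced per ``MedlineCitation`` (or ``PubmedArticle``)
    record, in file order.  The abstract is the concatenation of all
    ``AbstractText`` segments joined by single spaces; records with no
    abstract yield ``abstract == ""``.  Records lacking a PMID are skipped
    with a logged warning rather than assigned synthetic identifiers.

    Raises
    ------
    ValueError
        If the XML is malformed; the message names the byte offset
        reported by the parser.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    elif isinstance(source, (str, Path)):
        source = open(source, "rb")

    docs: list[Document] = []
    try:
        context = etree.iterparse(source, events=("end",), tag="MedlineCitation")
        for _event, elem in context:
            doc = _citation_to_document(elem)
            if doc is not None:
                docs.append(doc)
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        offset = getattr(exc, "position", None)
        raise ValueError(
            f"malformed XML near line {exc.lineno}, column {exc.offset} "
            f"(position {offset}): {exc.msg}"
        ) from exc
    finally:
        if hasattr(source, "close"):
            source.close()
    return docs


def _citation_to_document(elem: etree._Element) -> Document | None:
    pmid_el = elem.find("PMID")
    pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
    if not pmid:
        logger.warning("skipping citation record without PMID")
        return None
    title_el = elem.find(".//ArticleTitle")
    title = "".join(title_el.itertext()).strip() if title_el is not None else ""
    segments = [
        "".join(seg.itertext()).strip() for seg in elem.findall(".//AbstractText")
    ]
    abstract = " ".join(s for s in segments if s)
    return Document(doc_id=pmid, title=title, abstract=abstract)


def write_pubmed_xml(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as MedlineCitation-dialect XML (fixture writer).

    Emits the same XML subset :func:`parse_pubmed_xml` reads, so a
    write/parse round trip is the identity on (doc_id, title, abstract).
    """
    root = etree.Element("PubmedArticleSet")
    for doc in docs:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = doc.doc_id
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = doc.title
        if doc.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = doc.abstract
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Relation tables (TSV: doc_id, entity_name, entity_type)
# ---------------------------------------------------------------------------

_RELATION_COLUMNS = ("doc_id", "entity_name", "entity_type")


def read_relation_table(path: str | Path) -> list[RelationRecord]:
    """Read a tab-separated paper-entity relation table.

    Expects a header row with columns ``doc_id``, ``entity_name``,
    ``entity_type`` (UTF-8).  Entity types are matched case-insensitively
    against disease/drug/gene; rows with an unknown type token are
    rejected, counted and reported via a logged warning.  An empty file
    (header only, or zero bytes) yields an empty list.
    """
    records: list[RelationRecord] = []
    rejected = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        missing = [c for c in _RELATION_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"{path}: relation table missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                records.append(
                    RelationRecord(
                        doc_id=row[cols["doc_id"]].strip(),
                        entity_name=row[cols["entity_name"]].strip(),
                        entity_type=EntityType.parse(row[cols["entity_type"]]),
                    )
                )
            except (ValueError, IndexError) as exc:
                rejected += 1
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
    if rejected:
        logger.warning("%s: %d row(s) rejected", path, rejected)
    return records


def write_relation_table(records: Iterable[RelationRecord], path: str | Path) -> None:
    """Write relation records as the TSV dialect read_relation_table reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_RELATION_COLUMNS)
        for rec in records:
            writer.writerow([rec.doc_id, rec.entity_name, rec.entity_type.value])


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

# Filler vocabulary: ordinary discourse words that no reasonable
# disease/drug/gene dictionary contains; keeps planted ground truth exact.
_FILLER_WORDS = (
    "patients cohort baseline observed measured compared treated analysis "
    "significant outcomes findings results evaluated assessed reported "
    "clinical samples tissue serum levels expression elevated reduced "
    "median survival months groups control randomized prospective "
    "retrospective methods conclusions background associated correlated"
).split()

# Synthetic name stems; combined with per-type suffixes to yield surface
# forms that are pronounceable, unique, and absent from the filler list.
_NAME_STEMS = (
    "vorbal mextrin caldor zephrin quilost brundal taxilor fenwick "
    "ostrel gavrin helmid jorpax kresting lomendra nuvexi pralto "
    "quorvan rostilb sernova trivald ulmexor wendrap xalorin yendrel "
    "zorvix amplist borogat cindrel dovemar estrilon farexin girondol"
).split()

_TYPE_SUFFIX = {
    EntityType.DISEASE: "osis",
    EntityType.DRUG: "inib",
    EntityType.GENE: "gene",
}


@dataclass
class SyntheticCorpusConfig:
    """Settings for the planted-entity corpus generator.

    Defaults describe a small two-community literature: two groups of
    papers about disjoint entity sets, one high-frequency "hub" entity
    inside the first community, and one "bridge" entity that is the sole
    entity mentioned by papers of more than one community.
    """

    n_docs: int = 60
    n_communities: int = 2
    #: entities planted per type in each community
    entities_per_type: dict[EntityType, int] = field(
        default_factory=lambda: {
            EntityType.DISEASE: 4,
            EntityType.DRUG: 3,
            EntityType.GENE: 3,
        }
    )
    #: inclusive range of per-entity target document frequency; dense
    #: enough that each community's literature is mostly one component,
    #: so cross-community traffic concentrates on the bridge
    doc_freq_range: tuple[int, int] = (4, 8)
    #: plant a hub entity whose document frequency is hub_factor x the
    #: maximum ordinary frequency (confined to community 0)
    plant_hub: bool = True
    hub_type: EntityType = EntityType.DISEASE
    hub_factor: int = 3
    #: plant a bridge entity appearing in bridge_docs_per_community
    #: documents of every community (the only cross-community entity)
    plant_bridge: bool = True
    bridge_type: EntityType = EntityType.GENE
    bridge_docs_per_community: int = 4
    #: fraction of entities rendered with a hyphenated two-part surface
    #: form (exercises normalization during extraction)
    hyphenated_fraction: float = 0.25

    def validate(self) -> None:
        lo, hi = self.doc_freq_range
        docs_per_comm = self.n_docs // self.n_communities
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if lo < 1 or hi < lo:
            raise ValueError("doc_freq_range must be a nonempty range of >= 1")
        if hi > docs_per_comm:
            raise ValueError(
                f"doc frequency up to {hi} infeasible with "
                f"{docs_per_comm} documents per community"
            )
        if self.plant_hub and self.hub_factor * hi > docs_per_comm:
            raise ValueError(
                f"hub frequency {self.hub_factor * hi} exceeds the "
                f"{docs_per_comm} documents of its community"
            )
        if self.plant_bridge and self.bridge_docs_per_community > docs_per_comm:
            raise ValueError("bridge_docs_per_community exceeds community size")


@dataclass
class SyntheticGroundTruth:
    """Exact record of what the generator planted.

    ``doc_entities`` maps every doc_id to its planted entity set, from
    which document frequencies and expected co-occurrence counts are
    recomputed by enumeration (no sampling approximation).
    """

    doc_entities: dict[str, set[tuple[str, EntityType]]]
    #: (entity_name, type, target document frequency)
    planted_hubs: list[tuple[str, EntityType, int]]
    #: (entity_name, type, number of communities bridged)
    planted_bridges: list[tuple[str, EntityType, int]]
    #: entity -> list of surface forms used in the text
    surface_forms: dict[tuple[str, EntityType], list[str]]
    #: doc_id -> community index
    doc_community: dict[str, int]

    @property
    def entities(self) -> set[tuple[str, EntityType]]:
        out: set[tuple[str, EntityType]] = set()
        for ents in self.doc_entities.values():
            out |= ents
        return out

    def doc_frequency(self) -> Counter:
        """Number of documents mentioning each entity."""
        freq: Counter = Counter()
        for ents in self.doc_entities.values():
            freq.update(ents)
        return freq

    def cooc_matrix_expected(self) -> Counter:
        """Expected document co-count per unordered entity pair."""
        cooc: Counter = Counter()
        for ents in self.doc_entities.values():
            ordered = sorted(ents)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    cooc[(a, b)] += 1
        return cooc

    def incidences(self) -> set[tuple[str, str, EntityType]]:
        """The planted (doc_id, entity_name, entity_type) triples."""
        return {
            (doc_id, name, etype)
            for doc_id, ents in self.doc_entities.items()
            for (name, etype) in ents
        }

    def relation_records(self) -> list[RelationRecord]:
        return sorted(
            RelationRecord(d, n, t) for (d, n, t) in self.incidences()
        )


def _make_entity_names(
    config: SyntheticCorpusConfig, rng: np.random.Generator
) -> dict[int, dict[EntityType, list[tuple[str, list[str]]]]]:
    """Allot (canonical name, surface forms) per community and type."""
    stems = list(_NAME_STEMS)
    rng.shuffle(stems)
    stem_iter = iter(stems)
    out: dict[int, dict[EntityType, list[tuple[str, list[str]]]]] = {}
    for comm in range(config.n_communities):
        out[comm] = {}
        for etype, count in config.entities_per_type.items():
            entries = []
            for _ in range(count):
                stem = next(stem_iter)
                if rng.random() < config.hyphenated_fraction:
                    # canonical "stem-osis alpha" style two-token name;
                    # rendered hyphenated in text half the time
                    canonical = f"{stem}{_TYPE_SUFFIX[etype]} type {comm + 1}"
                    hyphenated = f"{stem}{_TYPE_SUFFIX[etype]}-type-{comm + 1}"
                    surfaces = [canonical, canonical.title(), hyphenated]
                else:
                    base = f"{stem}{_TYPE_SUFFIX[etype]}"
                    canonical = base
                    surfaces = [base, base.capitalize(), base.upper()]
                entries.append((canonical, surfaces))
            out[comm][etype] = entries
    return out


def _compose_abstract(
    surfaces: Sequence[str], rng: np.random.Generator
) -> str:
    """Embed the given surface forms in filler sentences."""
    sentences: list[str] = []
    todo = list(surfaces)
    while todo:
        batch, todo = todo[:3], todo[3:]
        words = [str(w) for w in rng.choice(_FILLER_WORDS, size=4)]
        parts = [words[0].capitalize(), words[1]]
        for s in batch:
            parts.append(s)
            parts.append(str(rng.choice(_FILLER_WORDS)))
        parts.extend(words[2:])
        sentences.append(" ".join(parts) + ".")
    if not sentences:
        words = [str(w) for w in rng.choice(_FILLER_WORDS, size=6)]
        sentences.append(" ".join([words[0].capitalize()] + words[1:]) + ".")
    return " ".join(sentences)


def generate_synthetic_corpus(
    config: SyntheticCorpusConfig | None = None, seed: int = 0
) -> tuple[list[Document], SyntheticGroundTruth]:
    """Generate a corpus with planted entity mentions and exact ground truth.

    Deterministic given (config, seed).  Papers are partitioned into
    communities; each ordinary entity appears in a sampled subset of its
    community's papers at its target document frequency.  Optionally a
    hub entity (3x the document frequency of any other entity) and a
    bridge entity (the sole entity shared between communities) are
    planted, giving known winners for PageRank and betweenness rankings.
    """
    config = config or SyntheticCorpusConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    doc_ids = [f"{1000000 + i}" for i in range(config.n_docs)]
    doc_community = {
        doc_id: i % config.n_communities for i, doc_id in enumerate(doc_ids)
    }
    comm_docs: dict[int, list[str]] = {c: [] for c in range(config.n_communities)}
    for doc_id, comm in doc_community.items():
        comm_docs[comm].append(doc_id)

    names = _make_entity_names(config, rng)
    doc_entities: dict[str, set[tuple[str, EntityType]]] = {d: set() for d in doc_ids}
    surface_forms: dict[tuple[str, EntityType], list[str]] = {}

    lo, hi = config.doc_freq_range
    for comm in range(config.n_communities):
        for etype, entries in names[comm].items():
            for canonical, surfaces in entries:
                key = (canonical, etype)
                surface_forms[key] = surfaces
                freq = int(rng.integers(lo, hi + 1))
                chosen = rng.choice(comm_docs[comm], size=freq, replace=False)
                for doc_id in chosen:
                    doc_entities[str(doc_id)].add(key)

    planted_hubs: list[tuple[str, EntityType, int]] = []
    if config.plant_hub:
        hub_key = ("cardinalosin hub", config.hub_type)
        surface_forms[hub_key] = ["cardinalosin hub", "Cardinalosin Hub"]
        hub_freq = config.hub_factor * hi
        chosen = rng.choice(comm_docs[0], size=hub_freq, replace=False)
        for doc_id in chosen:
            doc_entities[str(doc_id)].add(hub_key)
        planted_hubs.append((hub_key[0], config.hub_type, hub_freq))

    planted_bridges: list[tuple[str, EntityType, int]] = []
    if config.plant_bridge and config.n_communities >= 2:
        bridge_key = ("pontifexin bridge", config.bridge_type)
        surface_forms[bridge_key] = ["pontifexin bridge", "Pontifexin-Bridge"]
        for comm in range(config.n_communities):
            chosen = rng.choice(
                comm_docs[comm], size=config.bridge_docs_per_community, replace=False
            )
            for doc_id in chosen:
                doc_entities[str(doc_id)].add(bridge_key)
        planted_bridges.append(
            (bridge_key[0], config.bridge_type, config.n_communities)
        )

    docs: list[Document] = []
    for doc_id in doc_ids:
        ents = sorted(doc_entities[doc_id])
        rendered = [
            str(rng.choice(surface_forms[key])) for key in ents
        ]
        rng.shuffle(rendered)
        title_words = [str(w) for w in rng.choice(_FILLER_WORDS, size=3)]
        title_parts = [title_words[0].capitalize()]
        if rendered:
            title_parts.append(rendered[0])
        title_parts.extend(title_words[1:])
        title = " ".join(title_parts) + "."
        abstract = _compose_abstract(rendered[1:], rng)
        docs.append(Document(doc_id=doc_id, title=title, abstract=abstract))

    ground_truth = SyntheticGroundTruth(
        doc_entities=doc_entities,
        planted_hubs=planted_hubs,
        planted_bridges=planted_bridges,
        surface_forms=surface_forms,
        doc_community=doc_community,
    )
    return docs, ground_truth
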