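"""Type-specific entity dictionaries with string normalization.

Dictionaries map a *normalized* surface form to a canonical entity name.
Normalization is deliberately aggressive and lossy: case folding,
removal of the characters ``+ * ; _``, replacement of ``-`` by a space,
and whitespace collapsing — this lets "Beta-Catenin", "beta catenin" and
"BETA-CATENIN" all hit the same dictionary key.  Dictionaries for
different sources (e.g. a CTD export plus a PubTator-derived list) are
merged with first-wins collision handling so callers can order sources
by authority.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from litnet.corpus_io import EntityType

__all__ = ["Lexicon", "normalize_term", "load_dictionary", "merge_lexicons"]

_SPECIALS = re.compile(r"[+*;_]")
_WS = re.compile(r"\s+")
# dash punctuation (hyphens, en/em dashes, minus sign) folded to ASCII '-'
_DASHES = re.compile(r"[‐-―−⁃﹣－]")


def normalize_term(raw: str) -> str:
    """Normalize a surface string to its dictionary-key form.

    Applies, in order: NFKC unicode folding plus dash folding (so
    typographic hyphens and fullwidth characters match their ASCII
    forms), case folding, removal of ``+ * ; _``, replacement of ``-``
    by a space, collapsing runs of whitespace to one space, and
    stripping.  Total function; some inputs normalize to the empty
    string.  Idempotent, and invariant under upper/lower-casing of the
    input.
    """
    s = unicodedata.normalize("NFKC", raw)
    s = _DASHES.sub("-", s)
    # casefold + re-compose keeps keys stable under case changes that
    # alter composition (e.g. letters whose uppercase is decomposed)
    s = unicodedata.normalize("NFKC", s.casefold())
    s = _SPECIALS.sub("", s)
    s = s.replace("-", " ")
    s = _WS.sub(" ", s).strip()
    return s


@dataclass
class Lexicon:
    """A normalized-form → canonical-name dictionary for one entity type."""

    entity_type: EntityType
    entries: dict[str, str] = field(default_factory=dict)

    @property
    def max_token_length(self) -> int:
        """Token count of the longest normalized entry (1 if empty)."""
        if not self.entries:
            return 1
        return max(len(key.split()) for key in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, normalized: str) -> bool:
        return normalized in self.entries

    def lookup(self, normalized: str) -> str | None:
        return self.entries.get(normalized)

    def add(self, surface: str, canonical: str) -> bool:
        """Add one surface form; returns False if it normalizes to nothing
        or the key already exists (first entry wins)."""
        key = normalize_term(surface)
        if not key or key in self.entries:
            return False
        self.entries[key] = canonical
        return True

    @classmethod
    def from_terms(
        cls, entity_type: EntityType, terms: dict[str, str] | list[str]
    ) -> "Lexicon":
        """Build from {surface: canonical} or a plain list of names."""
        lex = cls(entity_type=entity_type)
        if isinstance(terms, dict):
            for surface, canonical in terms.items():
                lex.add(surface, canonical)
        else:
            for name in terms:
                lex.add(name, name)
        return lex

    def dump(self, path: str | Path) -> None:
        """Write as a two-column TSV (normalized_form, canonical_name)."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["normalized_form", "canonical_name"])
            for key in sorted(self.entries):
                writer.writerow([key, self.entries[key]])


def load_dictionary(
    path: str | Path,
    entity_type: EntityType | str,
    *,
    name_column: int = 0,
    synonym_column: int | None = 1,
    synonym_sep: str = "|",
) -> Lexicon:
    """Load a CTD-compatible delimited dictionary file.

    The delimiter is autodetected from the extension (``.csv`` → comma,
    otherwise tab).  Each row contributes its primary name and every
    pipe-delimited synonym as surface forms, all mapping to the primary
    name.  Surface forms that normalize to the empty string are dropped
    and counted.  Rows starting with ``#`` are comments.

    Raises
    ------
    OSError
        If the file cannot be read (message names the path).
    ValueError
        If no valid entries result.
    """
    if not isinstance(entity_type, EntityType):
        entity_type = EntityType.parse(entity_type)
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    lex = Lexicon(entity_type=entity_type)
    dropped = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for row in reader:
            if not row or row[0].lstrip().startswith("#"):
                continue
            primary = row[name_column].strip()
            if not primary:
                continue
            surfaces = [primary]
            if synonym_column is not None and len(row) > synonym_column:
                surfaces.extend(
                    s.strip() for s in row[synonym_column].split(synonym_sep) if s.strip()
                )
            for surface in surfaces:
                if not lex.add(surface, primary) and not normalize_term(surface):
                    dropped += 1
    if not lex.entries:
        raise ValueError(f"{path}: no valid dictionary entries")
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "%s: %d surface form(s) normalized to empty and were dropped",
            path,
            dropped,
        )
    return lex


def merge_lexicons(a: Lexicon, b: Lexicon) -> Lexicon:
    """Union two same-type lexicons; on key collision ``a`` wins.

    The merged size obeys ``|a ∪ b| = |a| + |b| − |a ∩ b|``.  First-wins
    lets callers place the more authoritative source first.
    """
    if a.entity_type != b.entity_type:
        raise ValueError(
            f"cannot merge lexicons of types {a.entity_type.value!r} "
            f"and {b.entity_type.value!r}"
        )
    merged = dict(b.entries)
    merged.update(a.entries)  # a overrides b on collisions
    return Lexicon(entity_type=a.entity_type, entries=merged)
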