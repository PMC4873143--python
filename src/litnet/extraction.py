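"""Dictionary-based entity extraction from titles and abstracts.

The extraction pipeline has four deterministic stages:

1. **sentence splitting** — rule-based, abbreviation-aware;
2. **tokenization** — Penn-Treebank-flavoured: punctuation is split off
   words, but intra-word hyphens are kept (``p53-mediated`` is one
   token; dictionary normalization later maps ``-`` to a space, so
   hyphenated tokens still match multi-word dictionary keys);
3. **lemmatization** — a rule-based English noun lemmatizer (plural
   stripping plus a small irregular table).  Lemmas are used only as a
   fallback when the surface n-gram misses the dictionary, which keeps
   lemmatizer quirks from creating false positives;
4. **matching** — left-to-right greedy longest match of normalized token
   n-grams against each type lexicon, non-overlapping within a type.

Matching granularity is document-level: repeated mentions of an entity
inside one paper collapse to a single paper-entity relation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from litnet.corpus_io import Document, EntityType, RelationRecord
from litnet.lexicon import Lexicon, normalize_term

__all__ = [
    "Token",
    "Mention",
    "split_sentences",
    "tokenize",
    "lemmatize",
    "match_entities",
    "extract_document",
    "extract_corpus",
]


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    sentence_index: int
    token_index: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.sentence_index < 0 or self.token_index < 0:
            raise ValueError("token indices must be nonnegative")


@dataclass(frozen=True)
class Mention:
    """An entity occurrence located in a document.

    ``span`` is a half-open (start_token, end_token) interval within the
    sentence given by ``sentence_index``.
    """

    doc_id: str
    entity_type: EntityType
    canonical_name: str
    matched_text: str
    sentence_index: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("mention span must be non-empty")


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# Common abbreviations after which a period does not end a sentence.
_ABBREVIATIONS = {
    "al",
    "approx",
    "ca",
    "cf",
    "dr",
    "e.g",
    "eg",
    "et",
    "etc",
    "fig",
    "figs",
    "i.e",
    "ie",
    "mr",
    "mrs",
    "no",
    "prof",
    "resp",
    "spp",
    "vs",
}

_SENT_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def split_sentences(text: str) -> list[str]:
    """Split plain text into sentences.

    A ``. ! ?`` run followed by whitespace ends a sentence unless the
    preceding word is a known abbreviation or a single letter (so
    ``E. coli`` and ``et al.`` do not split), or the following character
    is lowercase.  The concatenation of the output reconstructs the
    input up to inter-sentence whitespace.  Empty text yields ``[]``.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.end(1)
        nxt = text[match.end() : match.end() + 1]
        if nxt and not (nxt.isupper() or nxt.isdigit() or nxt in "\"'(["):
            continue
        prev_word = re.search(r"(\S+)$", text[start : match.start(1)])
        if prev_word:
            word = prev_word.group(1).rstrip(".").lstrip("([\"'")
            # single uppercase letters are initials ("E. coli"), not ends
            if word.lower() in _ABBREVIATIONS or (len(word) == 1 and word.isupper()):
                continue
        sentences.append(text[start:end].strip())
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Decimal numbers stay whole; words keep internal hyphens, apostrophes
# and slashes ("p53-mediated", "5'-UTR"); other punctuation is emitted
# one character at a time.
_TOKEN = re.compile(
    r"\d+\.\d+|[A-Za-z0-9À-ɏ]+(?:[-'/+][A-Za-z0-9À-ɏ]+)*|\S"
)


def tokenize(sentence: str, sentence_index: int = 0) -> list[Token]:
    """Tokenize one sentence into :class:`Token` objects with lemmas."""
    tokens = []
    for i, match in enumerate(_TOKEN.finditer(sentence)):
        surface = match.group(0)
        tokens.append(
            Token(
                surface=surface,
                lemma=lemmatize(surface),
                sentence_index=sentence_index,
                token_index=i,
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Lemmatization
# ---------------------------------------------------------------------------

_IRREGULAR_LEMMAS = {
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "analyses": "analysis",
    "diagnoses": "diagnosis",
    "metastases": "metastasis",
    "prognoses": "prognosis",
    "hypotheses": "hypothesis",
    "carcinomata": "carcinoma",
    "data": "datum",
    "criteria": "criterion",
    "phenomena": "phenomenon",
}


def lemmatize(word: str) -> str:
    """Deterministic rule-based lemma for an English word (lowercased).

    Handles noun plurals (``-ies`` → ``-y``, ``-ches/-shes/-xes/-sses``
    → strip ``-es``, plain ``-s`` stripping) plus a small irregular
    table.  Verbs and adjectives are left alone: lemma matching is only
    a dictionary fallback and biomedical dictionary entries are nouns.
    """
    w = word.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and (
        w.endswith("ches") or w.endswith("shes") or w.endswith("xes")
        or w.endswith("sses") or w.endswith("zes")
    ):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


# ---------------------------------------------------------------------------
# Dictionary matching
# ---------------------------------------------------------------------------


def match_entities(
    tokens: Sequence[Token],
    lexicons: Sequence[Lexicon],
    doc_id: str = "",
    precedence: Sequence[EntityType] | None = None,
) -> list[Mention]:
    """Greedy longest-match dictionary lookup over normalized n-grams.

    For each lexicon independently, scans each sentence left to right;
    at each position the longest window (up to the lexicon's
    ``max_token_length``) whose normalized surface n-gram — or, failing
    that, normalized lemma n-gram — is a dictionary key produces a
    mention, and the scan resumes after it.  Matched spans therefore do
    not overlap within one entity type.  A string present in several
    type lexicons yields one mention per type unless ``precedence`` is
    given, in which case earlier types claim overlapping spans.

    Raises ``ValueError`` on an empty lexicon list.
    """
    if not lexicons:
        raise ValueError("at least one lexicon is required")
    ordered = list(lexicons)
    if precedence is not None:
        rank = {t: i for i, t in enumerate(precedence)}
        ordered.sort(key=lambda lx: rank.get(lx.entity_type, len(rank)))

    by_sentence: dict[int, list[Token]] = {}
    for tok in tokens:
        by_sentence.setdefault(tok.sentence_index, []).append(tok)

    mentions: list[Mention] = []
    claimed: dict[int, set[int]] = {}  # sentence -> claimed positions (precedence mode)
    for sent_idx in sorted(by_sentence):
        sent = sorted(by_sentence[sent_idx], key=lambda t: t.token_index)
        for lex in ordered:
            maxlen = lex.max_token_length
            i = 0
            n = len(sent)
            while i < n:
                hit = None
                for length in range(min(maxlen, n - i), 0, -1):
                    window = sent[i : i + length]
                    if precedence is not None and any(
                        t.token_index in claimed.get(sent_idx, set()) for t in window
                    ):
                        continue
                    surf_key = normalize_term(" ".join(t.surface for t in window))
                    canonical = lex.lookup(surf_key)
                    if canonical is None:
                        lemma_key = normalize_term(" ".join(t.lemma for t in window))
                        canonical = lex.lookup(lemma_key)
                    if canonical is not None:
                        hit = (length, canonical, window)
                        break
                if hit is None:
                    i += 1
                    continue
                length, canonical, window = hit
                mentions.append(
                    Mention(
                        doc_id=doc_id,
                        entity_type=lex.entity_type,
                        canonical_name=canonical,
                        matched_text=" ".join(t.surface for t in window),
                        sentence_index=sent_idx,
                        span=(window[0].token_index, window[-1].token_index + 1),
                    )
                )
                if precedence is not None:
                    claimed.setdefault(sent_idx, set()).update(
                        t.token_index for t in window
                    )
                i += length
    return mentions


def extract_document(
    doc: Document,
    lexicons: Sequence[Lexicon],
    precedence: Sequence[EntityType] | None = None,
) -> list[Mention]:
    """Run the full pipeline on one document (title + abstract)."""
    tokens: list[Token] = []
    for s_idx, sentence in enumerate(split_sentences(doc.text)):
        tokens.extend(tokenize(sentence, sentence_index=s_idx))
    if not tokens:
        return []
    return match_entities(tokens, lexicons, doc_id=doc.doc_id, precedence=precedence)


def extract_corpus(
    docs: Iterable[Document],
    lexicons: Sequence[Lexicon],
    precedence: Sequence[EntityType] | None = None,
) -> list[RelationRecord]:
    """Extract document-level paper-entity relations from a corpus.

    One record per distinct (doc_id, canonical_name, entity_type):
    repeated mentions within a paper are deduplicated.  Output is sorted
    by (doc_id, entity_type, canonical_name).
    """
    seen: set[tuple[str, str, EntityType]] = set()
    for doc in docs:
        for mention in extract_document(doc, lexicons, precedence=precedence):
            seen.add((doc.doc_id, mention.canonical_name, mention.entity_type))
    triples = sorted((d, t.value, n) for (d, n, t) in seen)
    return [
        RelationRecord(doc_id=d, entity_name=n, entity_type=EntityType(t))
        for (d, t, n) in triples
    ]
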