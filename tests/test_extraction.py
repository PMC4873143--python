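"""Sentence splitting, tokenization, lemmatization and dictionary matching."""

import itertools
import random
import string

import pytest

from litnet.corpus_io import Document, EntityType
from litnet.extraction import (
    Token,
    extract_corpus,
    extract_document,
    lemmatize,
    match_entities,
    split_sentences,
    tokenize,
)
from litnet.lexicon import Lexicon, normalize_term


class TestSplitSentences:
    @pytest.mark.parametrize(
        "text, expected_count",
        [
            ("A b. C d.", 2),
            ("", 0),
            ("   ", 0),
            ("One sentence without terminal punctuation", 1),
            ("E. coli grows.", 1),
            ("Samples from E. coli were used. They grew well.", 2),
            ("See Fig. 2 for details.", 1),
            ("Treatment worked (p < 0.05). Survival improved.", 2),
            ("Mice et al. were treated. Controls were not.", 2),
            ("What happened? It improved! Then it stabilised.", 3),
        ],
    )
    def test_sentence_counts(self, text, expected_count):
        assert len(split_sentences(text)) == expected_count

    def test_concatenation_reconstructs_input_modulo_whitespace(self):
        text = "First result here. Second result there. Third, with e.g. caveats."
        sentences = split_sentences(text)
        assert " ".join(sentences) == text

    def test_deterministic(self):
        text = "A b. C d. E f."
        assert split_sentences(text) == split_sentences(text)


class TestTokenize:
    def test_hyphenated_word_is_one_token(self):
        surfaces = [t.surface for t in tokenize("p53-mediated apoptosis.")]
        assert surfaces == ["p53-mediated", "apoptosis", "."]

    def test_punctuation_split_from_words(self):
        assert [t.surface for t in tokenize("HCC,")] == ["HCC", ","]

    @pytest.mark.parametrize(
        "sentence, expected_count",
        [
            # hand-counted token tallies
            ("Hepatocellular carcinoma (HCC) is common.", 8),
            ("We evaluated sorafenib; results follow.", 7),
            ("TP53 and beta-catenin were mutated.", 6),
            ("Survival was 5.2 months.", 5),
            ("Doses of 5-FU/leucovorin varied.", 5),
        ],
    )
    def test_hand_counted_token_tallies(self, sentence, expected_count):
        assert len(tokenize(sentence)) == expected_count

    def test_indices_are_sequential(self):
        tokens = tokenize("One two three.", sentence_index=4)
        assert [t.token_index for t in tokens] == [0, 1, 2, 3]
        assert all(t.sentence_index == 4 for t in tokens)

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            Token(surface="", lemma="", sentence_index=0, token_index=0)


class TestLemmatize:
    @pytest.mark.parametrize(
        "word, lemma",
        [
            ("carcinomas", "carcinoma"),
            ("studies", "study"),
            ("branches", "branch"),
            ("boxes", "box"),
            ("classes", "class"),
            ("metastases", "metastasis"),
            ("mice", "mouse"),
            ("virus", "virus"),  # -us retained
            ("analysis", "analysis"),  # -is retained
            ("Genes", "gene"),
        ],
    )
    def test_noun_plurals(self, word, lemma):
        assert lemmatize(word) == lemma


def _tok(sentence: str) -> list[Token]:
    return tokenize(sentence)


class TestMatchEntities:
    def test_longest_match_wins(self):
        lex = Lexicon.from_terms(
            EntityType.DISEASE, ["hepatocellular carcinoma", "carcinoma"]
        )
        mentions = match_entities(_tok("hepatocellular carcinoma was observed"), [lex])
        assert len(mentions) == 1
        assert mentions[0].canonical_name == "hepatocellular carcinoma"

    def test_no_dictionary_words_no_mentions(self):
        lex = Lexicon.from_terms(EntityType.DRUG, ["sorafenib"])
        assert match_entities(_tok("nothing relevant here"), [lex]) == []

    def test_hyphenated_surface_matches_multiword_key(self):
        lex = Lexicon.from_terms(EntityType.GENE, ["beta catenin"])
        mentions = match_entities(_tok("Beta-Catenin signaling"), [lex])
        assert [m.canonical_name for m in mentions] == ["beta catenin"]

    def test_lemma_fallback_matches_plural(self):
        lex = Lexicon.from_terms(EntityType.DISEASE, ["carcinoma"])
        mentions = match_entities(_tok("two carcinomas were found"), [lex])
        assert [m.matched_text for m in mentions] == ["carcinomas"]

    def test_cross_type_string_yields_mention_per_type(self):
        drug = Lexicon.from_terms(EntityType.DRUG, ["abc"])
        gene = Lexicon.from_terms(EntityType.GENE, ["abc"])
        mentions = match_entities(_tok("abc was studied"), [drug, gene])
        assert {m.entity_type for m in mentions} == {EntityType.DRUG, EntityType.GENE}

    def test_precedence_suppresses_lower_ranked_types(self):
        drug = Lexicon.from_terms(EntityType.DRUG, ["abc"])
        gene = Lexicon.from_terms(EntityType.GENE, ["abc"])
        mentions = match_entities(
            _tok("abc was studied"),
            [gene, drug],
            precedence=[EntityType.DRUG, EntityType.GENE],
        )
        assert [m.entity_type for m in mentions] == [EntityType.DRUG]

    def test_empty_lexicon_list_rejected(self):
        with pytest.raises(ValueError):
            match_entities(_tok("anything"), [])

    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_brute_force_on_short_sentences(self, seed):
        """Greedy scan equals exhaustive maximal-match enumeration on
        sentences of at most 15 tokens."""
        rng = random.Random(seed)
        vocab = ["alpha", "beta", "gamma", "delta", "kappa", "sigma"]
        entries = set()
        for _ in range(rng.randint(2, 6)):
            entries.add(" ".join(rng.sample(vocab, rng.randint(1, 3))))
        lex = Lexicon.from_terms(EntityType.GENE, sorted(entries))
        sentence = " ".join(rng.choices(vocab + ["filler", "x1"], k=rng.randint(1, 15)))
        tokens = _tok(sentence)

        # oracle: enumerate every span, keep dictionary hits, then select
        # left-to-right preferring longer spans, skipping overlaps
        hits = []
        for start, end in itertools.combinations(range(len(tokens) + 1), 2):
            window = tokens[start:end]
            key = normalize_term(" ".join(t.surface for t in window))
            if key not in lex:
                key = normalize_term(" ".join(t.lemma for t in window))
            if key in lex:
                hits.append((start, end, lex.lookup(key)))
        chosen = []
        pos = 0
        while pos < len(tokens):
            starting = [h for h in hits if h[0] == pos]
            if not starting:
                pos += 1
                continue
            best = max(starting, key=lambda h: h[1])
            chosen.append(best)
            pos = best[1]

        mentions = match_entities(tokens, [lex])
        assert [(m.span[0], m.span[1], m.canonical_name) for m in mentions] == chosen


class TestExtractCorpus:
    def test_repeated_mentions_deduplicate_to_one_record(self):
        doc = Document("1", "HCC and HCC.", "More about HCC.")
        lex = Lexicon.from_terms(EntityType.DISEASE, ["HCC"])
        records = extract_corpus([doc], [lex])
        assert len(records) == 1
        assert records[0].doc_id == "1"

    def test_disjoint_documents_are_additive(self):
        docs = [
            Document("1", "Sorafenib works.", ""),
            Document("2", "TP53 is mutated.", ""),
        ]
        lexicons = [
            Lexicon.from_terms(EntityType.DRUG, ["sorafenib"]),
            Lexicon.from_terms(EntityType.GENE, ["TP53"]),
        ]
        records = extract_corpus(docs, lexicons)
        assert len(records) == 2

    def test_output_sorted_and_unique(self, synthetic_corpus, synthetic_lexicons):
        docs, _truth = synthetic_corpus
        records = extract_corpus(docs, synthetic_lexicons)
        keys = [(r.doc_id, r.entity_type.value, r.entity_name) for r in records]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)

    def test_exact_recovery_of_planted_incidences(self, synthetic_corpus, synthetic_lexicons):
        """Precision and recall are both 1 on the synthetic corpus: the
        filler vocabulary is dictionary-free by construction."""
        docs, truth = synthetic_corpus
        records = extract_corpus(docs, synthetic_lexicons)
        recovered = {(r.doc_id, r.entity_name, r.entity_type) for r in records}
        assert recovered == truth.incidences()

    def test_title_and_abstract_both_scanned(self):
        lex = Lexicon.from_terms(EntityType.DRUG, ["sorafenib", "cisplatin"])
        doc = Document("9", "Sorafenib trial.", "Cisplatin comparison arm.")
        names = {m.canonical_name for m in extract_document(doc, [lex])}
        assert names == {"sorafenib", "cisplatin"}
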