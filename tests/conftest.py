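import pytest

from litnet.corpus_io import EntityType, SyntheticCorpusConfig, generate_synthetic_corpus
from litnet.lexicon import Lexicon


def lexicons_for(ground_truth) -> list[Lexicon]:
    """Build the three type lexicons covering a synthetic ground truth."""
    return [
        Lexicon.from_terms(
            etype,
            sorted(name for (name, t) in ground_truth.entities if t == etype),
        )
        for etype in EntityType
    ]


@pytest.fixture(scope="session")
def synthetic_corpus():
    """A default two-community corpus with planted hub and bridge."""
    docs, truth = generate_synthetic_corpus(SyntheticCorpusConfig(), seed=42)
    return docs, truth


@pytest.fixture(scope="session")
def synthetic_lexicons(synthetic_corpus):
    _docs, truth = synthetic_corpus
    return lexicons_for(truth)
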