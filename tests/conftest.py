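import pytest
from hypothesis import settings

from medrec.corpus_io import ClinicalNote
from medrec.synthetic import GeneratorConfig, generate_corpus, generate_lexicon_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    """Small deterministic lexicon fixture with the hand-written real entries."""
    return generate_lexicon_fixture(size=12, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """A small noisy corpus with gold annotations and links (default noise)."""
    return generate_corpus(GeneratorConfig(n_patients=8, seed=21))


@pytest.fixture(scope="session")
def clean_corpus():
    """A noise-free corpus: the oracle-solvable configuration."""
    return generate_corpus(
        GeneratorConfig(n_patients=20, abbreviation_rate=0.0, misspelling_rate=0.0, seed=5)
    )


@pytest.fixture()
def baclofen_note():
    return ClinicalNote("n1", "e1", "p1", "overview", "Baclofen 5 mg tab po bid")
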