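import pytest

from worknarr import (
    ConceptModelParams,
    ConceptTagModel,
    GeneratorParams,
    LabeledCorpus,
    NarrativeRecord,
    generate_corpus,
)


@pytest.fixture(scope="session")
def toy_corpus() -> LabeledCorpus:
    """Six tiny narratives: three work (factory/forklift), three other."""
    rows = [
        ("1", "fell at factory", "work"),
        ("2", "forklift hit leg", "work"),
        ("3", "cut hand at factory", "work"),
        ("4", "fell at home", "other"),
        ("5", "cut hand at home", "other"),
        ("6", "dog bite at park", "other"),
    ]
    return LabeledCorpus([NarrativeRecord(i, t, l) for i, t, l in rows], "toy")


@pytest.fixture(scope="session")
def toy_model(toy_corpus):
    params = ConceptModelParams(min_term_frequency=1, margin_floor=0.0)
    return ConceptTagModel(toy_corpus, params).fit()


@pytest.fixture(scope="session")
def synthetic_20k():
    """One moderately sized default-parameter corpus shared across tests."""
    corpus, annotations = generate_corpus(GeneratorParams(n_records=20_000, seed=7))
    return corpus, annotations
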