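import pytest

import chemner as cn
from chemner.lexicon import LexiconTerm


@pytest.fixture
def toy_lexicon() -> list[LexiconTerm]:
    """Small hand-built lexicon with controlled word overlap."""
    return [
        LexiconTerm("CHEBI:15377", "water", ("H2O", "aqua")),
        LexiconTerm("CHEBI:16236", "ethanol", ("ethyl alcohol",)),
        LexiconTerm("CHEBI:16240", "hydrogen peroxide", ()),
        LexiconTerm("CHEBI:17790", "methanol", ("methyl alcohol",)),
        LexiconTerm("CHEBI:30563", "zinc oxide", ()),
        LexiconTerm("CHEBI:27363", "zinc", ()),
    ]


@pytest.fixture(scope="session")
def separable_config() -> cn.FixtureConfig:
    """The study conditions for synthetic recovery: 10 documents, 50 terms,
    chemical-suffix entities against a plain-English background."""
    return cn.FixtureConfig(seed=1, n_docs=10, n_terms=50)


@pytest.fixture(scope="session")
def separable_lexicon(separable_config):
    return cn.make_lexicon(separable_config)


@pytest.fixture(scope="session")
def separable_corpus(separable_config, separable_lexicon):
    return cn.make_corpus(separable_lexicon, separable_config)


@pytest.fixture(scope="session")
def loocv_predictions(separable_corpus):
    """Leave-one-document-out CRF predictions over the fixture corpus.

    Session-scoped: this is the one genuinely expensive computation in the
    suite and several tests score it under different assessments.
    """
    return cn.leave_one_out(separable_corpus, cn.CrfConfig(seed=1))


@pytest.fixture(scope="session")
def dictionary_predictions(separable_corpus, separable_lexicon):
    return {
        d.doc_id: cn.recognize(separable_lexicon, d.text, d.doc_id)
        for d in separable_corpus
    }
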