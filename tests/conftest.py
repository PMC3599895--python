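import pytest

from corpuspool import (
    AnnotatedDocument,
    ConceptSpan,
    GuidelineProfile,
    SynthConfig,
    default_base_form_lexicon,
    default_concept_lexicon,
    default_term_dictionary,
    generate_corpus,
    tokenize,
)


@pytest.fixture(scope="session")
def concept_lexicon():
    return default_concept_lexicon()


@pytest.fixture(scope="session")
def base_forms():
    return default_base_form_lexicon()


@pytest.fixture(scope="session")
def term_dictionary(concept_lexicon, base_forms):
    return default_term_dictionary(concept_lexicon, base_forms)


@pytest.fixture()
def simple_doc():
    """One sentence with one two-token problem annotation."""
    line = "The patient denies any abdominal pain"
    doc = AnnotatedDocument(
        doc_id="note-1",
        lines=[tokenize(line, 0)],
        concepts=[ConceptSpan(0, 4, 5, "problem", "abdominal pain")],
    )
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def small_corpus(concept_lexicon):
    """A 12-document corpus under the default (no-extension) guideline."""
    return generate_corpus(
        concept_lexicon,
        GuidelineProfile(),
        SynthConfig(n_docs=12, seed=42),
        source_label="small",
    )


@pytest.fixture(scope="session")
def noisy_corpus(concept_lexicon):
    """A corpus whose guideline extends spans and merges phrases."""
    return generate_corpus(
        concept_lexicon,
        GuidelineProfile(p_article=0.2, p_possessive=0.05, p_merge_prep=0.5, p_merge_conj=0.5),
        SynthConfig(n_docs=12, seed=43),
        source_label="noisy",
    )
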