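"""Tokenization, standoff and CoNLL round-trips, manifests, statistics."""

import pytest

from corpuspool import (
    AnnotatedDocument,
    ConceptSpan,
    concept_token_fraction,
    from_conll,
    to_conll,
    tokenize,
)
from corpuspool.corpus_io import (
    AnnotationWarning,
    format_standoff,
    parse_standoff,
    read_corpus_manifest,
    save_corpus,
)


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        (
            "The patient denies any abdominal pain",
            ["The", "patient", "denies", "any", "abdominal", "pain"],
        ),
        ("", []),
        ("pain, fever.", ["pain", ",", "fever", "."]),
        ("chest-pain persists", ["chest-pain", "persists"]),
        ("(severe)", ["(", "severe", ")"]),
        ("B12 level", ["B12", "level"]),
        ("...", [".", ".", "."]),
    ],
)
def test_tokenize_splits_whitespace_and_edge_punctuation(raw, expected):
    tokens = tokenize(raw)
    assert [t.text for t in tokens] == expected
    assert [t.token_index for t in tokens] == list(range(len(expected)))


class TestStandoff:
    def test_record_coordinates_are_one_based_lines_zero_based_tokens(self):
        doc = parse_standoff(
            "The patient denies any abdominal pain\n",
            'c="abdominal pain" 1:4 1:5||t="problem"\n',
        )
        assert doc.concepts == [ConceptSpan(0, 4, 5, "problem", "abdominal pain")]

    def test_out_of_bounds_record_rejected_with_diagnostic(self):
        with pytest.warns(AnnotationWarning, match="out-of-bounds"):
            doc = parse_standoff(
                "The patient denies any abdominal pain\n",
                'c="pain" 1:4 1:99||t="problem"\n',
            )
        assert doc.concepts == []

    def test_malformed_record_rejected_with_line_number(self):
        with pytest.warns(AnnotationWarning, match="line 2"):
            doc = parse_standoff(
                "pain\n",
                'c="pain" 1:0 1:0||t="problem"\nnot a record\n',
            )
        assert len(doc.concepts) == 1

    def test_multi_line_record_rejected(self):
        with pytest.warns(AnnotationWarning, match="multi-line"):
            doc = parse_standoff("a b\nc d\n", 'c="b c" 1:1 2:0||t="problem"\n')
        assert doc.concepts == []

    def test_surface_mismatch_warns_and_rederives(self):
        with pytest.warns(AnnotationWarning, match="differs from tokens"):
            doc = parse_standoff("severe cough\n", 'c="mild cough" 1:0 1:1||t="problem"\n')
        assert doc.concepts[0].surface == "severe cough"

    def test_empty_annotation_file_gives_no_concepts(self):
        doc = parse_standoff("some text here\n", "")
        assert doc.concepts == []

    def test_write_sorts_concepts(self, simple_doc):
        simple_doc.concepts.append(ConceptSpan(0, 1, 1, "problem", "patient"))
        _, ann = format_standoff(simple_doc)
        lines = ann.splitlines()
        assert lines[0].startswith('c="patient" 1:1')
        assert lines[1].startswith('c="abdominal pain" 1:4')


def test_standoff_round_trip_on_generated_corpora(small_corpus, noisy_corpus):
    for corpus in (small_corpus, noisy_corpus):
        for doc in corpus:
            text, ann = format_standoff(doc)
            back = parse_standoff(text, ann, doc.doc_id, doc.report_type)
            assert [[t.text for t in l] for l in back.lines] == [
                [t.text for t in l] for l in doc.lines
            ]
            assert back.sorted_concepts() == doc.sorted_concepts()
            assert back.n_tokens == doc.n_tokens


class TestConll:
    def test_span_encodes_to_b_i_tail(self, simple_doc):
        out = to_conll(simple_doc)
        labels = [line.split("\t")[1] for line in out.splitlines() if line]
        assert labels == ["O", "O", "O", "O", "B", "I"]

    def test_round_trip_on_generated_corpus(self, small_corpus):
        for doc in small_corpus:
            back = from_conll(to_conll(doc), doc.doc_id)
            assert back.sorted_concepts() == [
                s for s in doc.sorted_concepts()
            ], doc.doc_id

    def test_leading_i_label_is_an_error(self):
        with pytest.raises(ValueError, match="I label without preceding"):
            from_conll("pain\tI\n")

    def test_overlapping_concepts_cannot_encode(self, simple_doc):
        simple_doc.concepts.append(ConceptSpan(0, 5, 5, "problem", "pain"))
        with pytest.raises(ValueError, match="overlapping"):
            to_conll(simple_doc)


def test_manifest_save_and_read_round_trip(tmp_path, small_corpus):
    manifest = save_corpus(small_corpus, tmp_path / "corpus")
    back = read_corpus_manifest(manifest)
    assert back.source_label == small_corpus.source_label
    assert back.doc_ids == small_corpus.doc_ids
    assert back.n_tokens == small_corpus.n_tokens
    assert back.n_concepts == small_corpus.n_concepts
    for a, b in zip(back, small_corpus):
        assert a.sorted_concepts() == b.sorted_concepts()
        assert a.report_type == b.report_type


def test_concept_token_fraction_counts_covered_tokens_once():
    doc = AnnotatedDocument(
        doc_id="d",
        lines=[tokenize("severe chest pain today", 0)],
        concepts=[
            ConceptSpan(0, 0, 2, "problem", "severe chest pain"),
            ConceptSpan(0, 1, 2, "problem", "chest pain"),
        ],
    )
    from corpuspool.corpus_io import Corpus

    assert concept_token_fraction(Corpus("c", [doc])) == pytest.approx(3 / 4)


def test_duplicate_doc_ids_rejected(small_corpus):
    from corpuspool.corpus_io import Corpus

    with pytest.raises(ValueError, match="duplicate doc_ids"):
        Corpus("dup", [small_corpus.documents[0], small_corpus.documents[0]])
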