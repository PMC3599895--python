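"""Guideline reconciliation: strip leading articles and possessive pronouns.

Annotation guidelines disagree on whether a concept phrase includes a
preceding article ("the cough") or possessive pronoun ("his cancer").
This module rectifies that difference automatically by shrinking every
annotation whose first token is such a stop word, leaving the span end
untouched. Only leading tokens are stripped, a span is never emptied,
and the operation is idempotent, so a curated corpus passes through
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus

__all__ = ["CurationConfig", "CurationReport", "curate_span", "curate_document", "curate_corpus"]

DEFAULT_ARTICLES = ("a", "the", "any", "some", "an", "this")
DEFAULT_POSSESSIVES = ("his", "her")


@dataclass(frozen=True)
class CurationConfig:
    articles: tuple[str, ...] = DEFAULT_ARTICLES
    possessives: tuple[str, ...] = DEFAULT_POSSESSIVES
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if not self.articles or not self.possessives:
            raise ValueError("article and possessive lists must be non-empty")
        for word in (*self.articles, *self.possessives):
            if word != word.lower():
                raise ValueError(f"stop-word lists must be lowercase: {word!r}")

    @property
    def stop_words(self) -> frozenset[str]:
        return frozenset(self.articles) | frozenset(self.possessives)


@dataclass(frozen=True)
class CurationReport:
    """How many spans the reconciliation touched."""

    n_total: int
    n_modified: int

    @property
    def fraction_modified(self) -> float:
        return self.n_modified / self.n_total if self.n_total else 0.0


def curate_span(
    span: ConceptSpan, doc: AnnotatedDocument, config: CurationConfig | None = None
) -> ConceptSpan:
    """Strip leading articles/possessives from one span (never emptying it)."""
    config = config or CurationConfig()
    stop = config.stop_words
    start = span.start_token
    while start < span.end_token:
        word = doc.lines[span.line_index][start].text
        if config.case_insensitive:
            word = word.lower()
        if word not in stop:
            break
        start += 1
    if start == span.start_token:
        return span
    new = replace(span, start_token=start)
    return replace(new, surface=doc.surface_of(new))


def curate_document(
    doc: AnnotatedDocument, config: CurationConfig | None = None
) -> tuple[AnnotatedDocument, CurationReport]:
    config = config or CurationConfig()
    curated: list[ConceptSpan] = []
    seen: set[tuple[int, int, int, str]] = set()
    n_modified = 0
    for span in doc.sorted_concepts():
        new = curate_span(span, doc, config)
        if new.key() != span.key():
            n_modified += 1
        if new.key() in seen:  # two spans collapsed onto one phrase
            continue
        seen.add(new.key())
        curated.append(new)
    out = AnnotatedDocument(
        doc_id=doc.doc_id, lines=doc.lines, concepts=curated, report_type=doc.report_type
    )
    return out, CurationReport(n_total=len(doc.concepts), n_modified=n_modified)


def curate_corpus(
    corpus: Corpus, config: CurationConfig | None = None, source_label: str | None = None
) -> tuple[Corpus, CurationReport]:
    """Curate every document; report counts spans whose bounds changed."""
    config = config or CurationConfig()
    docs = []
    n_total = n_modified = 0
    for doc in corpus:
        new_doc, report = curate_document(doc, config)
        docs.append(new_doc)
        n_total += report.n_total
        n_modified += report.n_modified
    label = source_label or f"{corpus.source_label}-curated"
    return Corpus(label, docs), CurationReport(n_total=n_total, n_modified=n_modified)
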