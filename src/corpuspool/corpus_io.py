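"""Containers and I/O for annotated clinical-note corpora.

A corpus is a collection of notes, each note a sequence of lines (one
sentence per line), each line a sequence of whitespace-free tokens.
Concept annotations ("medical problem" phrases) are stored stand-off,
addressed by (line, start token, end token) with inclusive token ends.
Two interchange formats are supported:

* an i2b2-style stand-off pair (``.txt`` + ``.con``) where each concept
  record reads ``c="<surface>" L:S L:E||t="<type>"`` with 1-based line
  numbers and 0-based token offsets, and
* CoNLL-style BIO files (``token<TAB>label``, blank line between
  sentences).

Internally everything is 0-based with inclusive span ends; the 1-based
line number appears only at the serialization boundary.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "AnnotationWarning",
    "Token",
    "ConceptSpan",
    "AnnotatedDocument",
    "Corpus",
    "tokenize",
    "parse_standoff",
    "format_standoff",
    "read_standoff",
    "write_standoff",
    "to_conll",
    "from_conll",
    "read_corpus_manifest",
    "save_corpus",
    "concept_token_fraction",
]


class AnnotationWarning(UserWarning):
    """Raised (as a warning) for recoverable annotation-record problems."""


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


@dataclass(frozen=True)
class Token:
    """A single whitespace-free token at a (line, position) coordinate."""

    text: str
    line_index: int
    token_index: int

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise ValueError(f"token text must be non-empty and whitespace-free: {self.text!r}")


@dataclass(frozen=True)
class ConceptSpan:
    """A concept annotation over tokens ``start_token..end_token`` (inclusive) of one line."""

    line_index: int
    start_token: int
    end_token: int
    semantic_type: str = "problem"
    surface: str = ""

    def __post_init__(self) -> None:
        if self.start_token > self.end_token:
            raise ValueError(f"empty span: start {self.start_token} > end {self.end_token}")

    @property
    def n_tokens(self) -> int:
        return self.end_token - self.start_token + 1

    def key(self) -> tuple[int, int, int, str]:
        """Identity of the span ignoring the informational surface string."""
        return (self.line_index, self.start_token, self.end_token, self.semantic_type)

    def sort_key(self) -> tuple[int, int, int, str]:
        return (self.line_index, self.start_token, self.end_token, self.semantic_type)

    def overlaps(self, other: "ConceptSpan") -> bool:
        return (
            self.line_index == other.line_index
            and self.start_token <= other.end_token
            and other.start_token <= self.end_token
        )


@dataclass
class AnnotatedDocument:
    """One clinical note: tokenized lines plus gold concept spans."""

    doc_id: str
    lines: list[list[Token]]
    concepts: list[ConceptSpan] = field(default_factory=list)
    report_type: str | None = None

    @property
    def n_tokens(self) -> int:
        return sum(len(line) for line in self.lines)

    def line_texts(self, line_index: int) -> list[str]:
        return [t.text for t in self.lines[line_index]]

    def surface_of(self, span: ConceptSpan) -> str:
        toks = self.lines[span.line_index][span.start_token : span.end_token + 1]
        return " ".join(t.text for t in toks)

    def concepts_of_type(self, semantic_type: str) -> list[ConceptSpan]:
        return [c for c in self.concepts if c.semantic_type == semantic_type]

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural-invariant violation."""
        for li, line in enumerate(self.lines):
            for ti, tok in enumerate(line):
                if tok.line_index != li or tok.token_index != ti:
                    raise ValueError(
                        f"{self.doc_id}: token at {li}:{ti} carries coordinates "
                        f"{tok.line_index}:{tok.token_index}"
                    )
        seen: set[tuple[int, int, int, str]] = set()
        for span in self.concepts:
            if span.line_index < 0 or span.line_index >= len(self.lines):
                raise ValueError(f"{self.doc_id}: span {span} outside document lines")
            if span.end_token >= len(self.lines[span.line_index]):
                raise ValueError(f"{self.doc_id}: span {span} outside line bounds")
            if span.key() in seen:
                raise ValueError(f"{self.doc_id}: duplicate concept {span.key()}")
            seen.add(span.key())
            derived = self.surface_of(span)
            if span.surface and span.surface != derived:
                raise ValueError(
                    f"{self.doc_id}: span surface {span.surface!r} != tokens {derived!r}"
                )

    def sorted_concepts(self) -> list[ConceptSpan]:
        return sorted(self.concepts, key=ConceptSpan.sort_key)


@dataclass
class Corpus:
    """A named set of annotated documents (e.g. the local or the foreign corpus)."""

    source_label: str
    documents: list[AnnotatedDocument]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids in corpus {self.source_label!r}: {dupes}")

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __getitem__(self, doc_id: str) -> AnnotatedDocument:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    @property
    def n_tokens(self) -> int:
        return sum(d.n_tokens for d in self.documents)

    @property
    def n_concepts(self) -> int:
        return sum(len(d.concepts) for d in self.documents)

    def subset(self, doc_ids: Iterable[str], source_label: str | None = None) -> "Corpus":
        wanted = list(doc_ids)
        missing = set(wanted) - set(self.doc_ids)
        if missing:
            raise KeyError(f"doc_ids not in corpus {self.source_label!r}: {sorted(missing)}")
        by_id = {d.doc_id: d for d in self.documents}
        return Corpus(source_label or self.source_label, [by_id[i] for i in wanted])

    def validate(self) -> None:
        for d in self.documents:
            d.validate()


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def tokenize(raw_line: str, line_index: int = 0) -> list[Token]:
    """Split one sentence line into tokens.

    Whitespace-delimited splitting, then leading/trailing punctuation
    characters are peeled off as individual tokens. Internal punctuation
    (hyphens, apostrophes, in-word slashes) is kept so "chest-pain" stays
    one token while "pain," becomes two.
    """
    pieces: list[str] = []
    for chunk in raw_line.split():
        start, end = 0, len(chunk)
        lead: list[str] = []
        while start < end and _is_punct(chunk[start]):
            lead.append(chunk[start])
            start += 1
        trail: list[str] = []
        while end > start and _is_punct(chunk[end - 1]):
            trail.append(chunk[end - 1])
            end -= 1
        pieces.extend(lead)
        if end > start:
            pieces.append(chunk[start:end])
        pieces.extend(reversed(trail))
    return [Token(text=p, line_index=line_index, token_index=i) for i, p in enumerate(pieces)]


# ---------------------------------------------------------------------------
# i2b2-style standoff
# ---------------------------------------------------------------------------

_CON_RE = re.compile(
    r'^c="(?P<surface>.*)" (?P<l1>\d+):(?P<s>\d+) (?P<l2>\d+):(?P<e>\d+)\|\|t="(?P<type>[^"]*)"$'
)


def parse_standoff(
    text: str,
    annotations: str,
    doc_id: str = "doc",
    report_type: str | None = None,
) -> AnnotatedDocument:
    """Build a document from standoff text and annotation strings.

    Malformed or out-of-bounds records are rejected with an
    :class:`AnnotationWarning` diagnostic; they never abort the read.
    """
    lines = [tokenize(raw, li) for li, raw in enumerate(text.splitlines())]
    doc = AnnotatedDocument(doc_id=doc_id, lines=lines, concepts=[], report_type=report_type)
    for lineno, record in enumerate(annotations.splitlines(), start=1):
        if not record.strip():
            continue
        m = _CON_RE.match(record.strip())
        if m is None:
            warnings.warn(
                f"{doc_id}: malformed annotation record at line {lineno}: {record!r}",
                AnnotationWarning,
                stacklevel=2,
            )
            continue
        l1, l2 = int(m["l1"]), int(m["l2"])
        start, end = int(m["s"]), int(m["e"])
        if l1 != l2:
            warnings.warn(
                f"{doc_id}: multi-line concept record rejected at line {lineno}: {record!r}",
                AnnotationWarning,
                stacklevel=2,
            )
            continue
        li = l1 - 1  # serialized lines are 1-based
        if not (0 <= li < len(lines)) or start > end or end >= len(lines[li]) or start < 0:
            warnings.warn(
                f"{doc_id}: out-of-bounds record at line {lineno}: {record!r}",
                AnnotationWarning,
                stacklevel=2,
            )
            continue
        span = ConceptSpan(li, start, end, m["type"])
        derived = doc.surface_of(span)
        if m["surface"] != derived:
            warnings.warn(
                f"{doc_id}: recorded surface {m['surface']!r} differs from tokens "
                f"{derived!r} at line {lineno}; using token-derived surface",
                AnnotationWarning,
                stacklevel=2,
            )
        doc.concepts.append(replace(span, surface=derived))
    return doc


def format_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document to (text, annotations) standoff strings."""
    text = "\n".join(" ".join(t.text for t in line) for line in doc.lines)
    if doc.lines:
        text += "\n"
    records = []
    for span in doc.sorted_concepts():
        surface = doc.surface_of(span)
        records.append(
            f'c="{surface}" {span.line_index + 1}:{span.start_token} '
            f'{span.line_index + 1}:{span.end_token}||t="{span.semantic_type}"'
        )
    annotations = "\n".join(records)
    if records:
        annotations += "\n"
    return text, annotations


def read_standoff(
    text_path: str | Path,
    annotation_path: str | Path,
    doc_id: str | None = None,
    report_type: str | None = None,
) -> AnnotatedDocument:
    text_path, annotation_path = Path(text_path), Path(annotation_path)
    return parse_standoff(
        text_path.read_text(encoding="utf-8"),
        annotation_path.read_text(encoding="utf-8"),
        doc_id=doc_id or text_path.stem,
        report_type=report_type,
    )


def write_standoff(
    doc: AnnotatedDocument, text_path: str | Path, annotation_path: str | Path
) -> None:
    text, annotations = format_standoff(doc)
    Path(text_path).write_text(text, encoding="utf-8")
    Path(annotation_path).write_text(annotations, encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-style BIO
# ---------------------------------------------------------------------------

def to_conll(doc: AnnotatedDocument, semantic_type: str = "problem") -> str:
    """Render one document as ``token<TAB>label`` lines, blank line per sentence.

    Concepts of the chosen type must be non-overlapping (BIO cannot express
    overlap); violations raise ``ValueError`` naming the colliding spans.
    """
    from .features import bio_encode  # local import to avoid a cycle

    out: list[str] = []
    for li, labels in enumerate(bio_encode(doc, semantic_type)):
        for tok, label in zip(doc.lines[li], labels):
            out.append(f"{tok.text}\t{label}")
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


def from_conll(
    text: str, doc_id: str = "doc", semantic_type: str = "problem"
) -> AnnotatedDocument:
    """Parse CoNLL BIO lines; an I label without a preceding B/I is an error."""
    lines: list[list[Token]] = []
    concepts: list[ConceptSpan] = []
    cur: list[str] = []

    def flush(sentence: list[tuple[str, str]], line_index: int, first_lineno: int) -> None:
        toks = [Token(text, line_index, i) for i, (text, _) in enumerate(sentence)]
        lines.append(toks)
        start: int | None = None
        for i, (_, label) in enumerate(sentence):
            if label == "B":
                if start is not None:
                    concepts.append(_mk(line_index, start, i - 1))
                start = i
            elif label == "I":
                if start is None:
                    raise ValueError(
                        f"{doc_id}: I label without preceding B/I at file line "
                        f"{first_lineno + i}"
                    )
            elif label == "O":
                if start is not None:
                    concepts.append(_mk(line_index, start, i - 1))
                    start = None
            else:
                raise ValueError(f"{doc_id}: unknown label {label!r} at file line {first_lineno + i}")
        if start is not None:
            concepts.append(_mk(line_index, start, len(sentence) - 1))

    def _mk(li: int, s: int, e: int) -> ConceptSpan:
        surface = " ".join(t.text for t in lines[li][s : e + 1])
        return ConceptSpan(li, s, e, semantic_type, surface)

    sentence: list[tuple[str, str]] = []
    first_lineno = 1
    line_index = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            if sentence:
                flush(sentence, line_index, first_lineno)
                line_index += 1
                sentence = []
            continue
        if not sentence:
            first_lineno = lineno
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{doc_id}: malformed CoNLL line {lineno}: {raw!r}")
        sentence.append((parts[0], parts[1]))
    if sentence:
        flush(sentence, line_index, first_lineno)
    return AnnotatedDocument(doc_id=doc_id, lines=lines, concepts=concepts)


# ---------------------------------------------------------------------------
# Manifests and statistics
# ---------------------------------------------------------------------------

def read_corpus_manifest(manifest_path: str | Path) -> Corpus:
    """Read a YAML corpus manifest.

    Schema::

        source_label: local
        documents:
          - text: notes/doc1.txt
            annotations: notes/doc1.con
            report_type: progress_note   # optional
    """
    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    base = manifest_path.parent
    docs = []
    for entry in spec["documents"]:
        docs.append(
            read_standoff(
                base / entry["text"],
                base / entry["annotations"],
                report_type=entry.get("report_type"),
            )
        )
    return Corpus(source_label=spec.get("source_label", manifest_path.stem), documents=docs)


def save_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write every document as standoff files plus a manifest; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for doc in corpus:
        write_standoff(doc, out_dir / f"{doc.doc_id}.txt", out_dir / f"{doc.doc_id}.con")
        entry: dict[str, str] = {
            "text": f"{doc.doc_id}.txt",
            "annotations": f"{doc.doc_id}.con",
        }
        if doc.report_type:
            entry["report_type"] = doc.report_type
        entries.append(entry)
    manifest = out_dir / "manifest.yaml"
    manifest.write_text(
        yaml.safe_dump({"source_label": corpus.source_label, "documents": entries}, sort_keys=False),
        encoding="utf-8",
    )
    return manifest


def concept_token_fraction(
    corpus: Corpus | AnnotatedDocument, semantic_type: str | None = None
) -> float:
    """Fraction of tokens lying inside a concept annotation.

    Tokens covered by several (overlapping) annotations are counted once.
    """
    docs = corpus.documents if isinstance(corpus, Corpus) else [corpus]
    covered = 0
    total = 0
    for doc in docs:
        total += doc.n_tokens
        per_line: dict[int, set[int]] = {}
        for span in doc.concepts:
            if semantic_type is not None and span.semantic_type != semantic_type:
                continue
            per_line.setdefault(span.line_index, set()).update(
                range(span.start_token, span.end_token + 1)
            )
        covered += sum(len(v) for v in per_line.values())
    return covered / total if total else 0.0
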