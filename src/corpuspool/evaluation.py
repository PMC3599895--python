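"""Span-level evaluation and inter-corpus phrase-overlap statistics.

Two matching regimes are supported for scoring predicted against gold
concept spans:

* ``exact`` — a predicted span matches a gold span only when both
  boundaries (and the semantic type) agree;
* ``overlap`` — any shared token suffices.

Matching is one-to-one: the score is derived from a *maximum* bipartite
pairing between predicted and gold spans under the regime's predicate,
so a single long prediction cannot claim several gold spans. Precision,
recall and F1 follow the usual definitions

    P = tp / (tp + fp),  R = tp / (tp + fn),  F1 = 2PR / (P + R)

with the zero-denominator convention P = R = F1 = 0.

Separately, :func:`phrase_overlap` measures how much two corpora's
annotation vocabularies agree, with optional leniency for one ignored
start word or one ignored word anywhere — the standard diagnostics for
guideline differences such as included articles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import ConceptSpan

__all__ = [
    "MatchResult",
    "PRF",
    "OverlapStats",
    "CorpusEvaluation",
    "pair_spans",
    "prf",
    "phrase_overlap",
    "evaluate_corpus",
]

MATCH_MODES = ("exact", "overlap")
OVERLAP_MODES = ("exact", "ignore_one_start_word", "ignore_one_word")


@dataclass(frozen=True)
class MatchResult:
    """One-to-one span-pairing counts under a matching mode."""

    mode: str
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.mode not in MATCH_MODES:
            raise ValueError(f"unknown match mode {self.mode!r}")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp

    @property
    def n_gold(self) -> int:
        return self.tp + self.fn

    def __add__(self, other: "MatchResult") -> "MatchResult":
        if self.mode != other.mode:
            raise ValueError(f"cannot add {self.mode!r} and {other.mode!r} counts")
        return MatchResult(self.mode, self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float


def prf(m: MatchResult) -> PRF:
    """Precision/recall/F1 from pairing counts, with zero conventions."""
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = 2 * r * p / (r + p) if (r + p) else 0.0
    return PRF(precision=p, recall=r, f1=f1)


def _compatible(a: ConceptSpan, b: ConceptSpan, mode: str) -> bool:
    if a.semantic_type != b.semantic_type:
        return False
    if mode == "exact":
        return (a.line_index, a.start_token, a.end_token) == (
            b.line_index,
            b.start_token,
            b.end_token,
        )
    return a.overlaps(b)


def _max_matching(pred: Sequence[ConceptSpan], gold: Sequence[ConceptSpan], mode: str) -> int:
    """Size of a maximum one-to-one pairing (augmenting-path algorithm)."""
    adj = [
        [j for j, g in enumerate(gold) if _compatible(p, g, mode)] for p in pred
    ]
    match_of_gold: list[int | None] = [None] * len(gold)

    def augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_of_gold[j] is None or augment(match_of_gold[j], seen):
                match_of_gold[j] = i
                return True
        return False

    size = 0
    for i in range(len(pred)):
        if augment(i, set()):
            size += 1
    return size


def pair_spans(
    predicted: Sequence[ConceptSpan], gold: Sequence[ConceptSpan], mode: str
) -> MatchResult:
    """Score predicted against gold spans of one document under ``mode``."""
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}; expected one of {MATCH_MODES}")
    tp = _max_matching(list(predicted), list(gold), mode)
    return MatchResult(mode=mode, tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


@dataclass(frozen=True)
class CorpusEvaluation:
    """Micro-averaged scores over a document collection, both regimes."""

    exact_counts: MatchResult
    overlap_counts: MatchResult

    @property
    def exact(self) -> PRF:
        return prf(self.exact_counts)

    @property
    def overlap(self) -> PRF:
        return prf(self.overlap_counts)

    def score(self, mode: str) -> PRF:
        if mode == "exact":
            return self.exact
        if mode == "overlap":
            return self.overlap
        raise ValueError(f"unknown match mode {mode!r}")


def evaluate_corpus(
    predictions: Mapping[str, Sequence[ConceptSpan]],
    gold: Mapping[str, Sequence[ConceptSpan]],
) -> CorpusEvaluation:
    """Micro-average: pairing counts are summed over documents, then scored."""
    if set(predictions) != set(gold):
        only_pred = sorted(set(predictions) - set(gold))
        only_gold = sorted(set(gold) - set(predictions))
        raise ValueError(
            f"document sets differ; prediction-only={only_pred}, gold-only={only_gold}"
        )
    exact = MatchResult("exact", 0, 0, 0)
    overlap = MatchResult("overlap", 0, 0, 0)
    for doc_id in sorted(gold):
        exact = exact + pair_spans(predictions[doc_id], gold[doc_id], "exact")
        overlap = overlap + pair_spans(predictions[doc_id], gold[doc_id], "overlap")
    return CorpusEvaluation(exact_counts=exact, overlap_counts=overlap)


# ---------------------------------------------------------------------------
# Annotation-phrase overlap between corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStats:
    mode: str
    n_source: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_source


def _variants(phrase: tuple[str, ...], mode: str) -> set[tuple[str, ...]]:
    out = {phrase}
    if len(phrase) >= 2:
        if mode == "ignore_one_start_word":
            out.add(phrase[1:])
        elif mode == "ignore_one_word":
            for i in range(len(phrase)):
                out.add(phrase[:i] + phrase[i + 1 :])
    return out


def phrase_overlap(
    source_phrases: Iterable[Sequence[str]],
    target_phrases: Iterable[Sequence[str]],
    mode: str = "exact",
) -> OverlapStats:
    """Fraction of source annotation phrases found among target phrases.

    ``source_phrases`` is a multiset (each occurrence counted); the target
    is treated as a set. A source phrase matches when some variant of it
    equals some variant of a target phrase, where variants depend on the
    mode: ``exact`` (none), ``ignore_one_start_word`` (the phrase minus its
    first token, either side), ``ignore_one_word`` (the phrase minus any
    single token, either side). Deletions apply only to phrases of length
    two or more; comparison is case-insensitive.
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap mode {mode!r}; expected one of {OVERLAP_MODES}")
    source = [tuple(w.lower() for w in p) for p in source_phrases]
    if not source:
        raise ValueError("phrase overlap is undefined for an empty source multiset")
    target_variants: set[tuple[str, ...]] = set()
    for p in {tuple(w.lower() for w in t) for t in target_phrases}:
        target_variants |= _variants(p, mode)
    matched = sum(
        1 for p in source if not _variants(p, mode).isdisjoint(target_variants)
    )
    return OverlapStats(mode=mode, n_source=len(source), n_matched=matched)


def corpus_phrases(corpus, semantic_type: str = "problem") -> list[tuple[str, ...]]:
    """All annotation surface phrases of a corpus as lowercased token tuples."""
    phrases: list[tuple[str, ...]] = []
    for doc in corpus:
        for span in doc.concepts:
            if span.semantic_type != semantic_type:
                continue
            toks = doc.lines[span.line_index][span.start_token : span.end_token + 1]
            phrases.append(tuple(t.text.lower() for t in toks))
    return phrases
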