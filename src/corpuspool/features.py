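"""BIO label codec, word shapes, POS fallback and token feature extraction.

Each token of a line is described by lexical features (word, lowercased
word, prefixes/suffixes up to length 4), orthographic features (word
shape and run-compressed shape, digit flag), a part-of-speech tag, and
the dictionary-lookup state (B/I per semantic label of the longest
covering dictionary match). The same inventory is repeated for the
neighbors at offsets -2..+2 — the five-token feature window — with
begin/end-of-line sentinels past the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Callable, Sequence

from .corpus_io import AnnotatedDocument, ConceptSpan
from .normalize import DictMatch

__all__ = [
    "BIO_LABELS",
    "FeatureConfig",
    "bio_encode",
    "bio_decode",
    "word_shape",
    "dict_match_states",
    "extract_features",
    "RuleBasedPOSTagger",
    "POSProvider",
]

BIO_LABELS = ("B", "I", "O")

#: Contract for pluggable POS tagging: token texts in, one tag per token out.
POSProvider = Callable[[Sequence[str]], list[str]]


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

def bio_encode(doc: AnnotatedDocument, semantic_type: str = "problem") -> list[list[str]]:
    """Per-line B/I/O labels for the concepts of ``semantic_type``.

    Raises ``ValueError`` if two concepts of that type overlap (BIO cannot
    represent overlapping spans).
    """
    labels = [["O"] * len(line) for line in doc.lines]
    by_line: dict[int, list[ConceptSpan]] = {}
    for span in doc.concepts_of_type(semantic_type):
        by_line.setdefault(span.line_index, []).append(span)
    for li, spans in by_line.items():
        spans.sort(key=ConceptSpan.sort_key)
        prev: ConceptSpan | None = None
        for span in spans:
            if prev is not None and span.start_token <= prev.end_token:
                raise ValueError(
                    f"{doc.doc_id}: overlapping {semantic_type!r} concepts "
                    f"{prev.key()} and {span.key()} cannot be BIO-encoded"
                )
            labels[li][span.start_token] = "B"
            for t in range(span.start_token + 1, span.end_token + 1):
                labels[li][t] = "I"
            prev = span
    return labels


def bio_decode(
    labels: Sequence[str],
    line_index: int,
    tokens: Sequence[str] | None = None,
    semantic_type: str = "problem",
) -> list[ConceptSpan]:
    """Spans from a BIO label sequence (tolerant: a stray I opens a span)."""
    spans: list[ConceptSpan] = []
    start: int | None = None
    for i, label in enumerate(labels):
        if label == "B" or (label == "I" and start is None):
            if start is not None:
                spans.append(_make_span(line_index, start, i - 1, tokens, semantic_type))
            start = i
        elif label == "O":
            if start is not None:
                spans.append(_make_span(line_index, start, i - 1, tokens, semantic_type))
                start = None
        elif label != "I":
            raise ValueError(f"unknown BIO label {label!r} at position {i}")
    if start is not None:
        spans.append(_make_span(line_index, start, len(labels) - 1, tokens, semantic_type))
    return spans


def _make_span(
    line_index: int, start: int, end: int, tokens: Sequence[str] | None, semantic_type: str
) -> ConceptSpan:
    surface = " ".join(tokens[start : end + 1]) if tokens is not None else ""
    return ConceptSpan(line_index, start, end, semantic_type, surface)


# ---------------------------------------------------------------------------
# Orthography
# ---------------------------------------------------------------------------

def word_shape(text: str) -> tuple[str, str]:
    """(shape, compressed shape): A/a/9/- per char, runs collapsed in the latter."""
    shape = "".join(
        "A" if ch.isupper() else "a" if ch.islower() else "9" if ch.isdigit() else "-"
        for ch in text
    )
    compressed = "".join(ch for ch, _ in groupby(shape))
    return shape, compressed


# ---------------------------------------------------------------------------
# Fallback POS tagging
# ---------------------------------------------------------------------------

_CLOSED_CLASS = {
    **{w: "DT" for w in ("the", "a", "an", "this", "that", "these", "those", "any",
                          "some", "no", "each", "every", "all", "both")},
    **{w: "PRP$" for w in ("his", "her", "their", "my", "your", "its", "our")},
    **{w: "PRP" for w in ("he", "she", "it", "they", "we", "you", "i", "him", "them")},
    **{w: "IN" for w in ("in", "of", "on", "at", "with", "for", "from", "to", "by",
                          "without", "during", "after", "before", "under", "over",
                          "since", "into", "per")},
    **{w: "CC" for w in ("and", "or", "but", "nor")},
    **{w: "MD" for w in ("will", "would", "can", "could", "may", "might", "should", "must")},
    **{w: "VBZ" for w in ("is", "has", "does", "denies", "reports", "presents", "states",
                           "notes", "complains", "shows", "reveals", "remains", "includes")},
    **{w: "VBD" for w in ("was", "were", "had", "did")},
    **{w: "VBP" for w in ("are", "have", "do", "feel", "report", "deny")},
    **{w: "RB" for w in ("not", "very", "well", "overall", "today", "yesterday", "again",
                          "still", "now", "here")},
}

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ing", "VBG"),
    ("ed", "VBD"),
    ("ly", "RB"),
    ("ous", "JJ"),
    ("ive", "JJ"),
    ("ful", "JJ"),
    ("able", "JJ"),
    ("al", "JJ"),
    ("ic", "JJ"),
)


class RuleBasedPOSTagger:
    """Deterministic closed-class + suffix heuristic tagger (default NN).

    A lightweight built-in provider satisfying the :data:`POSProvider`
    contract; any external tagger with the same signature can replace it.
    """

    name = "rule-based"

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        tags = []
        for text in tokens:
            low = text.lower()
            if low in _CLOSED_CLASS:
                tags.append(_CLOSED_CLASS[low])
            elif all(not ch.isalnum() for ch in text):
                tags.append(text if len(text) == 1 else "SYM")
            elif any(ch.isdigit() for ch in text) and not any(ch.isalpha() for ch in text):
                tags.append("CD")
            else:
                for suffix, tag in _SUFFIX_RULES:
                    if len(low) > len(suffix) + 2 and low.endswith(suffix):
                        tags.append(tag)
                        break
                else:
                    if len(low) > 3 and low.endswith("s"):
                        tags.append("NNS")
                    else:
                        tags.append("NN")
        return tags


# ---------------------------------------------------------------------------
# Dictionary-state and window features
# ---------------------------------------------------------------------------

def dict_match_states(n_tokens: int, matches: Sequence[DictMatch]) -> list[str]:
    """Per-token B-<label>/I-<label>/O from the longest covering match.

    Ties on length are broken by leftmost start, then lexicographic label,
    so the state sequence is a deterministic function of the match set.
    """
    best: list[DictMatch | None] = [None] * n_tokens
    for m in sorted(matches, key=lambda m: (-m.n_tokens, m.start_token, m.semantic_label)):
        for t in range(m.start_token, m.end_token + 1):
            if 0 <= t < n_tokens and best[t] is None:
                best[t] = m
    states = []
    for t, m in enumerate(best):
        if m is None:
            states.append("O")
        elif t == m.start_token:
            states.append(f"B-{m.semantic_label}")
        else:
            states.append(f"I-{m.semantic_label}")
    return states


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature-extraction parameters (fixed per trained model)."""

    window: int = 2  # neighbors at offsets -window..+window: five-token window
    affix_max: int = 4
    use_pos: bool = True
    use_dict: bool = True

    @property
    def offsets(self) -> range:
        return range(-self.window, self.window + 1)


def _base_features(
    text: str, pos: str | None, dict_state: str | None, config: FeatureConfig
) -> list[str]:
    low = text.lower()
    shape, cshape = word_shape(text)
    feats = [f"w={text}", f"low={low}", f"shape={shape}", f"cshape={cshape}"]
    for k in range(1, config.affix_max + 1):
        if len(low) >= k:
            feats.append(f"pre{k}={low[:k]}")
            feats.append(f"suf{k}={low[-k:]}")
    if text.isdigit():
        feats.append("isdigit")
    if pos is not None:
        feats.append(f"pos={pos}")
    if dict_state is not None:
        feats.append(f"dict={dict_state}")
    return feats


def extract_features(
    tokens: Sequence[str],
    dict_matches: Sequence[DictMatch] = (),
    pos_tags: Sequence[str] | None = None,
    config: FeatureConfig | None = None,
) -> list[list[str]]:
    """Feature strings for every token of one line.

    Returns, per token, a list of ``name@offset=value`` strings covering
    the centered window. ``pos_tags`` must align with ``tokens`` when POS
    features are enabled; ``dict_matches`` must belong to this line.
    """
    config = config or FeatureConfig()
    n = len(tokens)
    if config.use_pos:
        if pos_tags is None:
            raise ValueError("pos_tags required when use_pos is enabled")
        if len(pos_tags) != n:
            raise ValueError(f"pos_tags length {len(pos_tags)} != tokens length {n}")
    states = dict_match_states(n, dict_matches) if config.use_dict else None
    base = [
        _base_features(
            tokens[i],
            pos_tags[i] if config.use_pos else None,
            states[i] if states is not None else None,
            config,
        )
        for i in range(n)
    ]
    out: list[list[str]] = []
    for i in range(n):
        feats: list[str] = []
        for off in config.offsets:
            j = i + off
            if j < 0:
                feats.append(f"pad@{off}=BOS{-j}")
            elif j >= n:
                feats.append(f"pad@{off}=EOS{j - n + 1}")
            else:
                feats.extend(f"{f}@{off}" for f in base[j])
        out.append(feats)
    return out
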