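"""Lexical normalization and exhaustive dictionary lookup.

The dictionary-lookup stage matches a normalized term dictionary against
normalized note text. Normalization applies, in order: lowercasing,
removal of punctuation characters, mapping of Greek letters to the marker
``G``, mapping of digits to ``9``, and finally replacement by a base form
from a surface→lemma lexicon. Lookup reports *every* dictionary phrase
occurrence, including nested and overlapping ones.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import AnnotatedDocument, tokenize

__all__ = [
    "BaseFormLexicon",
    "TermDictionary",
    "DictMatch",
    "normalize_token",
    "build_dictionary",
    "lookup_all",
]


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def _is_greek(ch: str) -> bool:
    # Greek and Coptic block plus Greek Extended, letters only.
    return ("Ͱ" <= ch <= "Ͽ" or "ἀ" <= ch <= "῿") and unicodedata.category(
        ch
    ).startswith("L")


def _char_normalize(text: str) -> str:
    out = []
    for ch in text.lower():
        if _is_punct(ch):
            continue
        if _is_greek(ch):
            out.append("G")
        elif ch.isdigit():
            out.append("9")
        else:
            out.append(ch)
    return "".join(out)


class BaseFormLexicon:
    """Surface-form → base-form lexicon; absent keys map to themselves.

    Keys and values are character-normalized at load and value chains
    (a→b, b→c) are resolved to their terminal form, so that base-form
    replacement is a projection: applying it twice equals applying it once.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        raw = {_char_normalize(k): _char_normalize(v) for k, v in (mapping or {}).items()}
        self._map: dict[str, str] = {}
        for key in raw:
            value = raw[key]
            seen = {key}
            while value in raw and raw[value] != value and value not in seen:
                seen.add(value)
                value = raw[value]
            self._map[key] = value

    @classmethod
    def from_file(cls, path: str | Path) -> "BaseFormLexicon":
        """Read a ``surface<TAB>baseform`` file (UTF-8, # comments allowed)."""
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed lexicon line {lineno}: {raw!r}")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def base_form(self, surface: str) -> str:
        return self._map.get(surface, surface)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, surface: str) -> bool:
        return surface in self._map


_EMPTY_LEXICON = BaseFormLexicon()


def normalize_token(text: str, lexicon: BaseFormLexicon | None = None) -> str:
    """Normalize one token; may return "" for pure-punctuation tokens.

    Order: lowercase → strip punctuation → Greek letters → ``G`` →
    digits → ``9`` → base-form replacement. The result is stable under
    re-normalization for any Greek-free input (the Greek marker ``G`` is
    deliberately uppercase, matching dictionary convention, and is itself
    lowercased if fed back through).
    """
    lex = lexicon or _EMPTY_LEXICON
    return lex.base_form(_char_normalize(text))


@dataclass(frozen=True)
class DictMatch:
    """One dictionary phrase occurrence over document tokens (inclusive end)."""

    line_index: int
    start_token: int
    end_token: int
    semantic_label: str

    @property
    def n_tokens(self) -> int:
        return self.end_token - self.start_token + 1


@dataclass
class TermDictionary:
    """Normalized multi-token phrases with semantic labels.

    ``entries`` maps a normalized token tuple to the sorted set of labels
    attached to it. ``max_len`` bounds the lookup window length.
    """

    entries: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)
    _by_first: dict[str, list[tuple[str, ...]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._by_first = {}
        for phrase in self.entries:
            self._by_first.setdefault(phrase[0], []).append(phrase)

    @property
    def max_len(self) -> int:
        return max((len(p) for p in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: Sequence[str]) -> bool:
        return tuple(phrase) in self.entries

    def labels(self, phrase: Sequence[str]) -> tuple[str, ...]:
        return self.entries.get(tuple(phrase), ())

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[Sequence[str], str]],
        lexicon: BaseFormLexicon | None = None,
    ) -> "TermDictionary":
        """Build from (token-sequence, label) pairs, normalizing each token."""
        collected: dict[tuple[str, ...], set[str]] = {}
        for tokens, label in entries:
            norm = tuple(n for n in (normalize_token(t, lexicon) for t in tokens) if n)
            if not norm:
                continue
            collected.setdefault(norm, set()).add(label)
        return cls({p: tuple(sorted(ls)) for p, ls in collected.items()})

    @classmethod
    def from_terms(
        cls, terms: Iterable[tuple[str, str]], lexicon: BaseFormLexicon | None = None
    ) -> "TermDictionary":
        """Build from (raw term string, label) pairs using the shared tokenizer."""
        return cls.from_entries(
            (([t.text for t in tokenize(term)], label) for term, label in terms), lexicon
        )


def build_dictionary(
    term_path: str | Path, lexicon: BaseFormLexicon | None = None
) -> TermDictionary:
    """Read a ``term<TAB>label`` file into a normalized :class:`TermDictionary`."""
    terms: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(term_path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{term_path}: malformed term line {lineno}: {raw!r}")
        terms.append((parts[0], parts[1]))
    return TermDictionary.from_terms(terms, lexicon)


def lookup_all(
    doc: AnnotatedDocument,
    dictionary: TermDictionary,
    lexicon: BaseFormLexicon | None = None,
) -> list[DictMatch]:
    """Every dictionary phrase occurrence in the document, overlaps included.

    Windows run over tokens whose normalized form is non-empty (pure
    punctuation tokens are transparent), so a phrase may span an internal
    comma; reported spans always begin and end on content tokens. Matches
    are sorted by (line, start, end, label).
    """
    matches: list[DictMatch] = []
    max_len = dictionary.max_len
    if max_len == 0:
        return matches
    for li, line in enumerate(doc.lines):
        content = [
            (tok.token_index, norm)
            for tok in line
            if (norm := normalize_token(tok.text, lexicon))
        ]
        for i, (start_idx, first_norm) in enumerate(content):
            candidates = dictionary._by_first.get(first_norm)
            if not candidates:
                continue
            window_max = min(max_len, len(content) - i)
            for phrase in candidates:
                k = len(phrase)
                if k > window_max:
                    continue
                if tuple(norm for _, norm in content[i : i + k]) == phrase:
                    end_idx = content[i + k - 1][0]
                    for label in dictionary.entries[phrase]:
                        matches.append(DictMatch(li, start_idx, end_idx, label))
    matches.sort(key=lambda m: (m.line_index, m.start_token, m.end_token, m.semantic_label))
    return matches
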