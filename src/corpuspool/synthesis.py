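"""Synthetic paired corpora emulating two annotation guidelines.

Real clinical corpora annotated for medical problems are access
restricted, so every experiment in this package runs on generated
corpora whose *guideline* is parametric. A document is a sequence of
template-built sentence lines; a controllable fraction of lines carries
one or more concept mentions drawn from a concept lexicon, steered so
that the fraction of tokens inside concept annotations tracks a target
density (defaults to 0.11, typical of problem-annotated clinical text).

The :class:`GuidelineProfile` reproduces the span-extent conventions on
which real guidelines are known to disagree:

* ``p_article`` / ``p_possessive`` — probability that an annotation is
  extended to include a preceding article ("the cough") or possessive
  pronoun ("his cancer"). The stop word is inserted into the text and
  covered by the gold span, so the underlying concept phrase is
  unchanged and automated curation can recover it exactly.
* ``p_unrelated`` — probability that a concept mention in a non-patient
  context (e.g. "cancer" inside "the cancer department") is annotated.
* ``p_merge_prep`` — probability that a concept followed by a
  prepositional phrase ("pain in the chest") is annotated as one long
  span rather than the bare concept head.
* ``p_merge_conj`` — probability that a conjunction list ("nausea,
  vomiting and diarrhea") is annotated as a single span rather than
  three.
* ``vocab_fraction`` — fraction of the master concept lexicon this
  guideline's corpus draws on, controlling vocabulary overlap between
  institutions.

Determinism: identical (lexicon, profile, config, stream key) give
byte-identical corpora. Random draws are consumed in a fixed order that
does not depend on the profile's probability values, so two corpora
generated with the same seed but different probabilities share their
underlying concept stream — the basis of the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus, Token, tokenize
from .normalize import BaseFormLexicon, TermDictionary

__all__ = [
    "ConceptLexicon",
    "GuidelineProfile",
    "SynthConfig",
    "default_concept_lexicon",
    "default_base_form_lexicon",
    "default_term_dictionary",
    "strict_guideline",
    "inclusive_guideline",
    "generate_corpus",
    "generate_paired_corpora",
    "annotation_length_histogram",
]

# Article / possessive inventories with observed-frequency weights
# (these are the words real problem annotations were found to begin with).
_ARTICLES = ("a", "the", "any", "some", "an", "this")
_ARTICLE_WEIGHTS = (562, 269, 154, 134, 126, 25)
_POSSESSIVES = ("his", "her")
_POSSESSIVE_WEIGHTS = (174, 200)

_ADJECTIVES = (
    "severe", "chronic", "acute", "mild", "intermittent", "persistent",
    "recurrent", "progressive", "occasional", "worsening",
)
_SITES = (
    "chest", "abdominal", "back", "joint", "pelvic", "shoulder",
    "knee", "epigastric", "flank", "neck",
)
_SYMPTOMS = ("pain", "swelling", "tenderness", "discomfort", "stiffness", "cramping")
_CONDITIONS = (
    "fever", "cough", "nausea", "vomiting", "diarrhea", "fatigue", "dizziness",
    "headache", "rash", "anemia", "hypertension", "diabetes", "pneumonia",
    "asthma", "bronchitis", "arthritis", "dermatitis", "migraine", "insomnia",
    "anxiety", "depression", "obesity", "sepsis", "cellulitis", "gastritis",
    "colitis", "hepatitis", "nephritis", "cystitis", "sinusitis", "tonsillitis",
    "pharyngitis", "neuropathy", "edema", "dyspnea", "palpitations", "syncope",
    "vertigo", "tinnitus", "pruritus", "jaundice", "hematuria", "dysuria",
    "constipation", "bloating", "wheezing", "malaise", "lethargy", "confusion",
    "tremor", "weakness", "cancer", "melanoma", "lymphoma", "gout",
)


@dataclass(frozen=True)
class ConceptLexicon:
    """Master inventory the generator draws concept mentions from."""

    phrases: tuple[tuple[str, ...], ...]
    prep_pairs: tuple[tuple[str, str], ...]  # (site, symptom) pairs among phrases
    filler_words: frozenset[str]

    def __post_init__(self) -> None:
        heads = {p[0] for p in self.phrases}
        forbidden = set(_ARTICLES) | set(_POSSESSIVES)
        if heads & forbidden:
            raise ValueError(f"concept phrases may not begin with stop words: {heads & forbidden}")
        flat = {w for p in self.phrases for w in p}
        if flat & self.filler_words:
            raise ValueError(
                f"concept vocabulary overlaps filler vocabulary: {sorted(flat & self.filler_words)[:5]}"
            )

    @property
    def n_phrases(self) -> int:
        return len(self.phrases)


def default_concept_lexicon() -> ConceptLexicon:
    """Roughly 180 one- to four-token 'medical problem' phrases."""
    phrases: list[tuple[str, ...]] = [(c,) for c in _CONDITIONS]
    phrases += [(s,) for s in _SYMPTOMS]
    prep_pairs = tuple((site, sym) for site in _SITES for sym in _SYMPTOMS[:3])
    phrases += [pair for pair in prep_pairs]
    phrases += [(adj, cond) for adj, cond in zip(_ADJECTIVES, _CONDITIONS[:10])]
    phrases += [
        (adj, site, sym)
        for adj, (site, sym) in zip(_ADJECTIVES * 2, prep_pairs[:20])
    ]
    phrases += [
        ("progressively", adj, site, sym)
        for adj, (site, sym) in zip(_ADJECTIVES[:5], prep_pairs[20:25])
    ]
    filler = {
        w
        for template_set in (_FILLER_TEMPLATES, _CONCEPT_TEMPLATES, _UNRELATED_TEMPLATES,
                             _PREP_TEMPLATES, _CONJ_TEMPLATES)
        for template in template_set
        for w in template
        if not w.startswith("{")
    }
    return ConceptLexicon(
        phrases=tuple(dict.fromkeys(phrases)),
        prep_pairs=prep_pairs,
        filler_words=frozenset(filler),
    )


def default_base_form_lexicon() -> BaseFormLexicon:
    """Plural → singular base forms for the concept vocabulary."""
    words = set(_CONDITIONS) | set(_SYMPTOMS) | set(_SITES)
    mapping = {w + "s": w for w in words if not w.endswith("s")}
    mapping.update({"fevers": "fever", "headaches": "headache", "rashes": "rash"})
    return BaseFormLexicon(mapping)


def default_term_dictionary(
    lexicon: ConceptLexicon | None = None,
    base_forms: BaseFormLexicon | None = None,
    coverage: float = 1.0,
    seed: int = 0,
) -> TermDictionary:
    """Domain dictionary over the master lexicon (optionally incomplete)."""
    lexicon = lexicon or default_concept_lexicon()
    phrases = list(lexicon.phrases)
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if coverage < 1.0:
        rng = np.random.default_rng([seed, 7919])
        keep = rng.permutation(len(phrases))[: max(1, round(coverage * len(phrases)))]
        phrases = [phrases[i] for i in sorted(keep)]
    return TermDictionary.from_entries(
        ((p, "problem") for p in phrases), base_forms or default_base_form_lexicon()
    )


# ---------------------------------------------------------------------------
# Guideline profiles and generator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuidelineProfile:
    """Parametric description of one institution's annotation guideline."""

    p_article: float = 0.0
    p_possessive: float = 0.0
    p_unrelated: float = 0.0
    p_merge_prep: float = 0.0
    p_merge_conj: float = 0.0
    vocab_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_article", "p_possessive", "p_unrelated", "p_merge_prep",
                     "p_merge_conj", "vocab_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_article + self.p_possessive > 1.0:
            raise ValueError("p_article + p_possessive may not exceed 1")
        if self.vocab_fraction <= 0.0:
            raise ValueError("vocab_fraction must be positive")


def strict_guideline(vocab_fraction: float = 0.8) -> GuidelineProfile:
    """Minimal-span convention: bare concept heads, non-patient mentions annotated.

    Mirrors a guideline mapped strictly to an ontology: no articles or
    possessives in spans, prepositional phrases and conjunction lists
    split, but disease words in organizational names annotated too.
    """
    return GuidelineProfile(
        p_article=0.0,
        p_possessive=0.0,
        p_unrelated=1.0,
        p_merge_prep=0.0,
        p_merge_conj=0.0,
        vocab_fraction=vocab_fraction,
    )


def inclusive_guideline(vocab_fraction: float = 0.8) -> GuidelineProfile:
    """Extended-span convention: articles/possessives inside spans, patient-only.

    11% of annotations begin with an article and 3% with a possessive
    pronoun (the rates observed in problem-annotated challenge data);
    trailing prepositional phrases are usually merged, conjunction lists
    sometimes; non-patient mentions are never annotated.
    """
    return GuidelineProfile(
        p_article=0.11,
        p_possessive=0.03,
        p_unrelated=0.0,
        p_merge_prep=0.8,
        p_merge_conj=0.5,
        vocab_fraction=vocab_fraction,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Size, density and mixture parameters of one generated corpus."""

    n_docs: int = 50
    lines_per_doc: int = 12
    concept_density: float = 0.11  # target fraction of tokens inside annotations
    report_type_mixture: tuple[tuple[str, float], ...] = (
        ("progress_note", 0.6),
        ("history_exam", 0.4),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.concept_density < 1.0:
            raise ValueError("concept_density must lie in (0, 1)")
        total = sum(w for _, w in self.report_type_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"report-type weights must sum to 1, got {total}")
        if self.n_docs < 1 or self.lines_per_doc < 1:
            raise ValueError("n_docs and lines_per_doc must be positive")


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

_FILLER_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("the", "patient", "was", "seen", "in", "clinic", "today"),
    ("he", "is", "doing", "well", "overall"),
    ("vital", "signs", "were", "stable", "on", "review"),
    ("follow", "up", "visit", "scheduled", "in", "two", "weeks"),
    ("medication", "list", "was", "reviewed", "and", "updated"),
    ("laboratory", "results", "were", "discussed", "with", "the", "patient"),
    ("she", "will", "return", "if", "symptoms", "develop"),
    ("the", "patient", "reports", "gradual", "improvement"),
    ("she", "denies", "recent", "travel"),
    ("examination", "revealed", "no", "abnormalities"),
    ("he", "was", "counseled", "on", "diet", "and", "exercise"),
    ("the", "plan", "was", "discussed", "in", "detail"),
)

_CONCEPT_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("the", "patient", "reports", "{C}"),
    ("she", "denies", "{C}", "at", "this", "time"),
    ("he", "presents", "with", "{C}"),
    ("examination", "revealed", "{C}"),
    ("history", "is", "notable", "for", "{C}"),
    ("patient", "admitted", "for", "evaluation", "of", "{C}"),
    ("assessment", "shows", "{C}", "improving", "slowly"),
    ("{C}", "was", "noted", "on", "review"),
    ("symptoms", "include", "{C}", "since", "last", "visit"),
    ("there", "is", "no", "evidence", "of", "{C}"),
)

_UNRELATED_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("she", "was", "referred", "to", "the", "{C}", "department"),
    ("he", "was", "transferred", "to", "the", "{C}", "unit", "yesterday"),
    ("records", "were", "requested", "from", "the", "{C}", "clinic"),
)

_PREP_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("the", "patient", "reports", "{P}"),
    ("she", "describes", "{P}", "for", "two", "days"),
    ("he", "complains", "of", "{P}"),
)

_CONJ_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("she", "reports", "{L}"),
    ("review", "of", "systems", "is", "positive", "for", "{L}"),
    ("he", "has", "had", "{L}", "this", "week"),
)

# Per report type: weights over concept-bearing line kinds.
_KIND_WEIGHTS: dict[str, tuple[tuple[str, float], ...]] = {
    "progress_note": (("concept", 0.82), ("unrelated", 0.06), ("prep", 0.07), ("conj", 0.05)),
    "history_exam": (("concept", 0.78), ("unrelated", 0.04), ("prep", 0.10), ("conj", 0.08)),
}
_DEFAULT_KIND_WEIGHTS = _KIND_WEIGHTS["progress_note"]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _vocab_subset(
    lexicon: ConceptLexicon, fraction: float, stream: Sequence[int]
) -> list[tuple[str, ...]]:
    n_keep = max(1, round(fraction * lexicon.n_phrases))
    rng = np.random.default_rng([*stream, 999983])
    order = rng.permutation(lexicon.n_phrases)[:n_keep]
    return [lexicon.phrases[i] for i in sorted(order)]


def _weighted_index(rng: np.random.Generator, weights: Sequence[float]) -> int:
    # One uniform draw regardless of the weight vector: keeps parallel
    # generator streams aligned across differing profiles.
    u = rng.random()
    total = float(sum(weights))
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w / total
        if u < acc:
            return i
    return len(weights) - 1


class _LineBuilder:
    """Token/span assembly for one sentence line."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.spans: list[tuple[int, int]] = []  # inclusive token ranges
        self.n_inserted = 0  # stop words inserted by the inclusion lottery

    def add(self, *words: str) -> None:
        self.words.extend(words)

    def add_lead(self, lead: str | None) -> None:
        if lead is not None:
            self.words.append(lead)
            self.n_inserted += 1

    def add_span(self, words: Sequence[str], lead: str | None = None) -> None:
        start = len(self.words)
        self.add_lead(lead)
        self.words.extend(words)
        self.spans.append((start, len(self.words) - 1))


def _draw_inclusion(rng: np.random.Generator, profile: GuidelineProfile) -> str | None:
    """One span-start lottery: returns the stop word to insert, or None.

    Always consumes exactly three draws (threshold, article word,
    possessive word) so streams stay aligned across profiles.
    """
    u = rng.random()
    art = _ARTICLES[_weighted_index(rng, _ARTICLE_WEIGHTS)]
    poss = _POSSESSIVES[_weighted_index(rng, _POSSESSIVE_WEIGHTS)]
    if u < profile.p_possessive:
        return poss
    if u < profile.p_possessive + profile.p_article:
        return art
    return None


def _build_line(
    kind: str,
    rng: np.random.Generator,
    profile: GuidelineProfile,
    vocab: list[tuple[str, ...]],
    one_token_pool: list[tuple[str, ...]],
    prep_pool: list[tuple[str, str]],
) -> tuple[_LineBuilder, int]:
    """Realize one line; returns the builder and its base concept-token count."""
    lb = _LineBuilder()
    if kind == "filler":
        t = _FILLER_TEMPLATES[rng.integers(len(_FILLER_TEMPLATES))]
        lb.add(*t)
        return lb, 0

    if kind == "concept":
        t = _CONCEPT_TEMPLATES[rng.integers(len(_CONCEPT_TEMPLATES))]
        phrase = vocab[rng.integers(len(vocab))]
        lead = _draw_inclusion(rng, profile)
        for w in t:
            if w == "{C}":
                lb.add_span(phrase, lead)
            else:
                lb.add(w)
        return lb, len(phrase)

    if kind == "unrelated":
        t = _UNRELATED_TEMPLATES[rng.integers(len(_UNRELATED_TEMPLATES))]
        phrase = one_token_pool[rng.integers(len(one_token_pool))]
        annotate = rng.random() < profile.p_unrelated
        for w in t:
            if w == "{C}":
                if annotate:
                    lb.add_span(phrase)
                else:
                    lb.add(*phrase)
            else:
                lb.add(w)
        return lb, len(phrase)

    if kind == "prep":
        t = _PREP_TEMPLATES[rng.integers(len(_PREP_TEMPLATES))]
        site, sym = prep_pool[rng.integers(len(prep_pool))]
        merge = rng.random() < profile.p_merge_prep
        lead = _draw_inclusion(rng, profile)
        for w in t:
            if w == "{P}":
                if merge:
                    lb.add_span((sym, "in", "the", site), lead)
                else:
                    lb.add_span((sym,), lead)
                    lb.add("in", "the", site)
            else:
                lb.add(w)
        return lb, 2  # site+symptom pair, counted like its 2-token phrase

    if kind == "conj":
        t = _CONJ_TEMPLATES[rng.integers(len(_CONJ_TEMPLATES))]
        idx = rng.choice(len(one_token_pool), size=3, replace=False)
        items = [one_token_pool[i] for i in idx]
        merge = rng.random() < profile.p_merge_conj
        leads = [_draw_inclusion(rng, profile) for _ in range(3)]
        for w in t:
            if w == "{L}":
                if merge:
                    start = len(lb.words)
                    lb.add_lead(leads[0])
                    lb.add(*items[0], ",")
                    lb.add(*items[1], "and")
                    lb.add(*items[2])
                    lb.spans.append((start, len(lb.words) - 1))
                else:
                    lb.add_span(items[0], leads[0])
                    lb.add(",")
                    lb.add_span(items[1], leads[1])
                    lb.add("and")
                    lb.add_span(items[2], leads[2])
            else:
                lb.add(w)
        return lb, 3

    raise ValueError(f"unknown line kind {kind!r}")


def generate_corpus(
    lexicon: ConceptLexicon | None = None,
    profile: GuidelineProfile | None = None,
    config: SynthConfig | None = None,
    source_label: str = "synthetic",
    stream_key: Sequence[int] | None = None,
) -> Corpus:
    """Generate one corpus under one guideline profile.

    Raises ``ValueError`` if the realized concept-token density deviates
    from the configured target by more than 0.03 (possible only for
    extreme profiles or very small corpora).
    """
    lexicon = lexicon or default_concept_lexicon()
    profile = profile or GuidelineProfile()
    config = config or SynthConfig()
    key = list(stream_key) if stream_key is not None else [config.seed]

    vocab = _vocab_subset(lexicon, profile.vocab_fraction, key)
    one_token_pool = [p for p in vocab if len(p) == 1] or [vocab[0]]
    prep_pool = [p for p in vocab if len(p) == 2 and p in set(lexicon.prep_pairs)]
    if not prep_pool:
        prep_pool = list(lexicon.prep_pairs[:1])
    report_types = [name for name, _ in config.report_type_mixture]
    report_weights = [w for _, w in config.report_type_mixture]

    # Corpus-level density steering on profile-independent base counts.
    base_total = 0
    base_concept = 0

    documents: list[AnnotatedDocument] = []
    for d in range(config.n_docs):
        rng = np.random.default_rng([*key, d])
        report_type = report_types[_weighted_index(rng, report_weights)]
        kind_names = [k for k, _ in _KIND_WEIGHTS.get(report_type, _DEFAULT_KIND_WEIGHTS)]
        kind_weights = [w for _, w in _KIND_WEIGHTS.get(report_type, _DEFAULT_KIND_WEIGHTS)]
        n_lines = int(rng.integers(max(1, config.lines_per_doc - 2), config.lines_per_doc + 3))
        lines: list[list[Token]] = []
        concepts: list[ConceptSpan] = []
        for li in range(n_lines):
            concept_bearing = base_concept <= config.concept_density * base_total
            if concept_bearing:
                kind = kind_names[_weighted_index(rng, kind_weights)]
            else:
                kind = "filler"
            lb, base_len = _build_line(kind, rng, profile, vocab, one_token_pool, prep_pool)
            # Steering counters exclude lottery-inserted stop words so that
            # profiles differing only in inclusion probabilities make
            # identical steering (and hence template) decisions.
            base_concept += base_len
            base_total += len(lb.words) - lb.n_inserted
            tokens = [Token(w, li, ti) for ti, w in enumerate(lb.words)]
            lines.append(tokens)
            for start, end in lb.spans:
                concepts.append(
                    ConceptSpan(li, start, end, "problem",
                                " ".join(w.text for w in tokens[start : end + 1]))
                )
        doc = AnnotatedDocument(
            doc_id=f"{source_label}-{d:04d}",
            lines=lines,
            concepts=concepts,
            report_type=report_type,
        )
        documents.append(doc)
    corpus = Corpus(source_label, documents)
    corpus.validate()

    from .corpus_io import concept_token_fraction

    realized = concept_token_fraction(corpus)
    if abs(realized - config.concept_density) > 0.03:
        raise ValueError(
            f"realized concept density {realized:.3f} deviates more than 0.03 "
            f"from target {config.concept_density:.3f}; templates cannot reach it"
        )
    return corpus


def generate_paired_corpora(
    lexicon: ConceptLexicon | None = None,
    profile_local: GuidelineProfile | None = None,
    profile_foreign: GuidelineProfile | None = None,
    config_local: SynthConfig | None = None,
    config_foreign: SynthConfig | None = None,
    shared_seed: int = 0,
) -> tuple[Corpus, Corpus]:
    """Two corpora over one master lexicon, emulating two institutions.

    Default profiles: a strict minimal-span guideline for the local
    corpus and an inclusive extended-span guideline for the foreign one.
    The sides draw their vocabulary subsets independently (overlap is
    governed by the two ``vocab_fraction`` values), use disjoint document
    streams and disjoint doc_ids, and by default the foreign corpus is
    four times the size of the local one.
    """
    lexicon = lexicon or default_concept_lexicon()
    profile_local = profile_local or strict_guideline()
    profile_foreign = profile_foreign or inclusive_guideline()
    config_local = config_local or SynthConfig(n_docs=30)
    config_foreign = config_foreign or SynthConfig(n_docs=4 * config_local.n_docs)
    local = generate_corpus(
        lexicon, profile_local, config_local,
        source_label="local", stream_key=[shared_seed, 0, config_local.seed],
    )
    foreign = generate_corpus(
        lexicon, profile_foreign, config_foreign,
        source_label="foreign", stream_key=[shared_seed, 1, config_foreign.seed],
    )
    return local, foreign


def annotation_length_histogram(corpus: Corpus) -> dict[int, int]:
    """Counts of annotation lengths in tokens (sorted by length)."""
    counts: dict[int, int] = {}
    for doc in corpus:
        for span in doc.concepts:
            counts[span.n_tokens] = counts.get(span.n_tokens, 0) + 1
    return dict(sorted(counts.items()))
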