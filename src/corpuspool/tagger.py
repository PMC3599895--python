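"""Training and decoding of the concept sequence tagger.

The tagger is a linear-chain model over per-token B/I/O labels: a
maximum-entropy (multinomial logistic regression) emission model over
hashed window features, combined with label-bigram transition scores
estimated from the training corpus, decoded by Viterbi. Structural
zeros forbid an I after O or at line start, so decoded label sequences
are always valid BIO.

Feature extraction (see :mod:`corpuspool.features`) is pure, and the
hashing vectorizer is stateless, so featurized documents can be cached
and reused across the many train/test cycles of the cross-validation
experiments. A dictionary-only baseline tagger (longest non-overlapping
lookup matches) is provided for reference.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction import FeatureHasher
from sklearn.linear_model import LogisticRegression

from .corpus_io import AnnotatedDocument, ConceptSpan, Corpus
from .features import (
    BIO_LABELS,
    FeatureConfig,
    POSProvider,
    RuleBasedPOSTagger,
    bio_decode,
    bio_encode,
    extract_features,
)
from .normalize import BaseFormLexicon, TermDictionary, lookup_all

__all__ = [
    "TaggerConfig",
    "DocFeatures",
    "SequenceTagger",
    "featurize_document",
    "featurize_corpus",
    "train",
    "predict",
    "DictionaryTagger",
]

_N_HASH_FEATURES = 2**16
_LABEL_INDEX = {label: i for i, label in enumerate(BIO_LABELS)}


@dataclass(frozen=True)
class TaggerConfig:
    """Model hyper-parameters; stored with the model and reused at predict time."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    target_type: str = "problem"
    c: float = 1.0            # inverse L2 regularization strength
    max_iter: int = 100
    transition_smoothing: float = 1.0  # add-k on label bigram counts


@dataclass
class DocFeatures:
    """Hashed features and gold labels for one document, line by line."""

    doc_id: str
    line_indices: list[int]  # document line index per featurized line
    line_tokens: list[list[str]]
    line_matrices: list[sp.csr_matrix]
    line_labels: list[np.ndarray]  # int-coded B/I/O per line

    @property
    def X(self) -> sp.csr_matrix:
        return sp.vstack(self.line_matrices, format="csr")

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(self.line_labels) if self.line_labels else np.empty(0, int)


def _hasher() -> FeatureHasher:
    return FeatureHasher(n_features=_N_HASH_FEATURES, input_type="string")


def featurize_document(
    doc: AnnotatedDocument,
    dictionary: TermDictionary | None,
    lexicon: BaseFormLexicon | None,
    pos_provider: POSProvider | None,
    config: TaggerConfig,
) -> DocFeatures:
    """Extract and hash window features (and gold labels) for one document."""
    fc = config.features
    pos_provider = pos_provider or (RuleBasedPOSTagger() if fc.use_pos else None)
    matches_by_line: dict[int, list] = {}
    if fc.use_dict and dictionary is not None:
        for m in lookup_all(doc, dictionary, lexicon):
            matches_by_line.setdefault(m.line_index, []).append(m)
    gold = bio_encode(doc, config.target_type)
    hasher = _hasher()
    line_indices: list[int] = []
    line_tokens: list[list[str]] = []
    line_matrices: list[sp.csr_matrix] = []
    line_labels: list[np.ndarray] = []
    for li, line in enumerate(doc.lines):
        tokens = [t.text for t in line]
        if not tokens:
            continue
        feats = extract_features(
            tokens,
            matches_by_line.get(li, ()),
            pos_provider(tokens) if fc.use_pos else None,
            fc,
        )
        line_indices.append(li)
        line_tokens.append(tokens)
        line_matrices.append(hasher.transform(feats).tocsr())
        line_labels.append(np.array([_LABEL_INDEX[l] for l in gold[li]], dtype=np.int64))
    return DocFeatures(doc.doc_id, line_indices, line_tokens, line_matrices, line_labels)


def featurize_corpus(
    corpus: Corpus,
    dictionary: TermDictionary | None = None,
    lexicon: BaseFormLexicon | None = None,
    pos_provider: POSProvider | None = None,
    config: TaggerConfig | None = None,
) -> dict[str, DocFeatures]:
    config = config or TaggerConfig()
    return {
        doc.doc_id: featurize_document(doc, dictionary, lexicon, pos_provider, config)
        for doc in corpus
    }


def _transition_scores(label_lines: Iterable[np.ndarray], smoothing: float) -> np.ndarray:
    """Log-probability matrix over (START + 3 labels) x 3 labels.

    Row 0 is line start; rows 1..3 condition on the previous label. An I
    after O or at line start is a structural zero (-inf).
    """
    counts = np.full((4, 3), smoothing)
    i_idx = _LABEL_INDEX["I"]
    o_idx = _LABEL_INDEX["O"]
    counts[0, i_idx] = 0.0
    counts[1 + o_idx, i_idx] = 0.0
    for labels in label_lines:
        prev = 0
        for lab in labels:
            counts[prev, lab] += 1
            prev = 1 + int(lab)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.log(counts) - np.log(counts.sum(axis=1, keepdims=True))
    return log_p


def _viterbi(emission_log_p: np.ndarray, transition_log_p: np.ndarray) -> list[str]:
    n, k = emission_log_p.shape
    score = transition_log_p[0] + emission_log_p[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + transition_log_p[1:] + emission_log_p[t][None, :]
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(k)]
    path = [int(np.argmax(score))]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return [BIO_LABELS[i] for i in path]


@dataclass
class SequenceTagger:
    """A trained sequence tagger plus everything needed to reapply it."""

    classifier: LogisticRegression
    transitions: np.ndarray
    config: TaggerConfig
    dictionary: TermDictionary | None
    lexicon: BaseFormLexicon | None
    pos_provider: POSProvider | None
    metadata: dict

    def predict_document(
        self, doc: AnnotatedDocument, features: DocFeatures | None = None
    ) -> list[ConceptSpan]:
        return predict(self, doc, features)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Pickle the model, with a JSON sidecar describing its configuration."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "config": {
                "target_type": self.config.target_type,
                "c": self.config.c,
                "max_iter": self.config.max_iter,
                "features": asdict(self.config.features),
            },
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str), encoding="utf-8"
        )

    @staticmethod
    def load(path: str | Path) -> "SequenceTagger":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, SequenceTagger):
            raise TypeError(f"{path} does not contain a SequenceTagger")
        return model


def train(
    corpus: Corpus | None = None,
    dictionary: TermDictionary | None = None,
    lexicon: BaseFormLexicon | None = None,
    pos_provider: POSProvider | None = None,
    config: TaggerConfig | None = None,
    seed: int = 0,
    features: Mapping[str, DocFeatures] | None = None,
) -> SequenceTagger:
    """Train a tagger on a corpus (or on pre-featurized documents).

    Deterministic given the corpus, configuration and seed. Raises
    ``ValueError`` when the training data contain no concept of the
    target type (there would be nothing to learn).
    """
    config = config or TaggerConfig()
    if features is None:
        if corpus is None:
            raise ValueError("either a corpus or pre-featurized documents are required")
        features = featurize_corpus(corpus, dictionary, lexicon, pos_provider, config)
    doc_feats = list(features.values())
    if not doc_feats:
        raise ValueError("empty training corpus")
    y = np.concatenate([df.y for df in doc_feats])
    if not np.any(y != _LABEL_INDEX["O"]):
        raise ValueError("training corpus has no concept of type "
                         f"{config.target_type!r}; nothing to learn")
    X = sp.vstack([df.X for df in doc_feats], format="csr")
    clf = LogisticRegression(
        C=config.c,
        solver="lbfgs",
        max_iter=config.max_iter,
        tol=1e-4,
        random_state=seed,
    )
    clf.fit(X, y)
    transitions = _transition_scores(
        (labels for df in doc_feats for labels in df.line_labels),
        config.transition_smoothing,
    )
    metadata = {
        "corpus_label": corpus.source_label if corpus is not None else "pre-featurized",
        "n_documents": len(doc_feats),
        "n_tokens": int(X.shape[0]),
        "seed": seed,
    }
    return SequenceTagger(
        classifier=clf,
        transitions=transitions,
        config=config,
        dictionary=dictionary,
        lexicon=lexicon,
        pos_provider=pos_provider,
        metadata=metadata,
    )


def predict(
    model: SequenceTagger,
    doc: AnnotatedDocument,
    features: DocFeatures | None = None,
) -> list[ConceptSpan]:
    """Decode concept spans of the model's target type for one document."""
    if features is None:
        features = featurize_document(
            doc, model.dictionary, model.lexicon, model.pos_provider, model.config
        )
    spans: list[ConceptSpan] = []
    present = model.classifier.classes_
    for li, tokens, X in zip(
        features.line_indices, features.line_tokens, features.line_matrices
    ):
        log_p_present = model.classifier.predict_log_proba(X)
        log_p = np.full((X.shape[0], len(BIO_LABELS)), -np.inf)
        log_p[:, present] = log_p_present
        labels = _viterbi(log_p, model.transitions)
        spans.extend(bio_decode(labels, li, tokens, model.config.target_type))
    return spans


class DictionaryTagger:
    """Baseline: longest non-overlapping dictionary matches as predictions.

    Greedy selection by (length descending, start ascending) over the
    exhaustive lookup output; used as the reference the learned tagger
    must beat, never as its implementation.
    """

    def __init__(
        self,
        dictionary: TermDictionary,
        lexicon: BaseFormLexicon | None = None,
        target_type: str = "problem",
    ) -> None:
        self.dictionary = dictionary
        self.lexicon = lexicon
        self.target_type = target_type

    def predict_document(self, doc: AnnotatedDocument) -> list[ConceptSpan]:
        matches = [
            m
            for m in lookup_all(doc, self.dictionary, self.lexicon)
            if m.semantic_label == self.target_type
        ]
        matches.sort(key=lambda m: (-m.n_tokens, m.line_index, m.start_token))
        taken: dict[int, set[int]] = {}
        spans: list[ConceptSpan] = []
        for m in matches:
            covered = taken.setdefault(m.line_index, set())
            rng = set(range(m.start_token, m.end_token + 1))
            if rng & covered:
                continue
            covered |= rng
            span = ConceptSpan(m.line_index, m.start_token, m.end_token, self.target_type)
            spans.append(
                ConceptSpan(
                    m.line_index,
                    m.start_token,
                    m.end_token,
                    self.target_type,
                    doc.surface_of(span),
                )
            )
        spans.sort(key=ConceptSpan.sort_key)
        return spans
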