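"""Training/testing designs: cross-validation, corpus pooling, learning curves.

All designs share one engine: per (repeat, fold), a tagger is trained on
the local training fraction — optionally truncated to a subset size and
optionally supplemented with the *entire* foreign corpus — and evaluated
on the held-out fold under both the exact and the overlap regime. The
foreign corpus never contributes test documents; a hard leakage guard
verifies that no test document reaches the training set. Everything is
deterministic given (corpora, seeds, configuration).

The learning-curve design runs three arms per local subset size —
local-only, local+foreign, local+curated-foreign — which is the
instrument for the central question: below which local corpus size does
pooling a guideline-divergent foreign corpus still help?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import ConceptSpan, Corpus
from .curation import CurationConfig, curate_corpus
from .evaluation import CorpusEvaluation, evaluate_corpus
from .features import POSProvider
from .normalize import BaseFormLexicon, TermDictionary
from .tagger import DocFeatures, TaggerConfig, featurize_corpus, predict, train

__all__ = [
    "FoldPlan",
    "PoolingSpec",
    "CellScore",
    "ExperimentResult",
    "LearningCurveResult",
    "make_folds",
    "run_cv",
    "run_cross_corpus",
    "run_learning_curve",
]


@dataclass(frozen=True)
class FoldPlan:
    """Seeded repeated k-fold assignment of documents to folds."""

    k: int
    repeats: int
    seed: int
    assignments: tuple[Mapping[str, int], ...]  # per repeat: doc_id -> fold

    def test_ids(self, repeat: int, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignments[repeat].items() if f == fold)

    def train_ids(self, repeat: int, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignments[repeat].items() if f != fold)


def make_folds(corpus: Corpus, k: int = 5, repeats: int = 3, seed: int = 0) -> FoldPlan:
    """Per repeat: seeded shuffle then round-robin, so fold sizes differ by <=1."""
    ids = sorted(corpus.doc_ids)
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} documents")
    assignments = []
    for r in range(repeats):
        rng = np.random.default_rng([seed, 23, r])
        order = [ids[i] for i in rng.permutation(len(ids))]
        assignments.append({doc_id: i % k for i, doc_id in enumerate(order)})
    return FoldPlan(k=k, repeats=repeats, seed=seed, assignments=tuple(assignments))


@dataclass
class PoolingSpec:
    """What to train on: a local corpus, optionally pooled with a foreign one."""

    local: Corpus
    foreign: Corpus | None = None
    curate_foreign: bool = False
    subset_size: int | None = None
    curation: CurationConfig = field(default_factory=CurationConfig)


@dataclass(frozen=True)
class CellScore:
    """Evaluation of one (repeat, fold) cell, both matching regimes."""

    repeat: int
    fold: int
    evaluation: CorpusEvaluation

    def value(self, mode: str, metric: str) -> float:
        return getattr(self.evaluation.score(mode), metric)


@dataclass
class ExperimentResult:
    """Per-cell scores plus provenance for one experimental design."""

    design: str
    cells: list[CellScore]
    provenance: dict

    def values(self, mode: str = "exact", metric: str = "f1") -> np.ndarray:
        return np.array([c.value(mode, metric) for c in self.cells])

    def mean(self, mode: str = "exact", metric: str = "f1") -> float:
        return float(self.values(mode, metric).mean())

    def std(self, mode: str = "exact", metric: str = "f1") -> float:
        return float(self.values(mode, metric).std(ddof=1)) if len(self.cells) > 1 else 0.0

    def repeat_means(self, mode: str = "exact", metric: str = "f1") -> np.ndarray:
        """Mean over folds, per repeat."""
        frame = self.to_frame()
        sub = frame[(frame["mode"] == mode)]
        return sub.groupby("repeat")[metric].mean().to_numpy()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            for mode in ("exact", "overlap"):
                score = cell.evaluation.score(mode)
                counts = (
                    cell.evaluation.exact_counts
                    if mode == "exact"
                    else cell.evaluation.overlap_counts
                )
                rows.append(
                    {
                        "design": self.design,
                        "repeat": cell.repeat,
                        "fold": cell.fold,
                        "mode": mode,
                        "precision": score.precision,
                        "recall": score.recall,
                        "f1": score.f1,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "fn": counts.fn,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame.groupby("mode")[["precision", "recall", "f1"]].agg(["mean", "std"])


def _check_dominance(evaluation: CorpusEvaluation, context: str) -> None:
    exact, overlap = evaluation.exact, evaluation.overlap
    for metric in ("precision", "recall", "f1"):
        if getattr(overlap, metric) < getattr(exact, metric) - 1e-12:
            raise RuntimeError(
                f"overlap {metric} fell below exact {metric} in {context}; "
                "the matching implementation is broken"
            )


def _evaluate_fold(
    model_features: dict[str, DocFeatures],
    test_docs: Sequence,
    test_features: Mapping[str, DocFeatures],
    config: TaggerConfig,
    seed: int,
) -> CorpusEvaluation:
    model = train(features=model_features, config=config, seed=seed)
    predictions = {
        doc.doc_id: predict(model, doc, test_features[doc.doc_id]) for doc in test_docs
    }
    gold = {doc.doc_id: doc.concepts_of_type(config.target_type) for doc in test_docs}
    return evaluate_corpus(predictions, gold)


def run_cv(
    spec: PoolingSpec,
    plan: FoldPlan | None = None,
    config: TaggerConfig | None = None,
    seed: int = 0,
    dictionary: TermDictionary | None = None,
    lexicon: BaseFormLexicon | None = None,
    pos_provider: POSProvider | None = None,
    local_features: Mapping[str, DocFeatures] | None = None,
    foreign_features: Mapping[str, DocFeatures] | None = None,
) -> ExperimentResult:
    """Repeated k-fold CV on the local corpus, optionally pooled with foreign.

    The foreign corpus (curated first if requested) is added whole to
    every training fold and never tested on. ``subset_size`` truncates
    the local training fraction (seeded, nested across sizes).
    """
    config = config or TaggerConfig()
    plan = plan or make_folds(spec.local, seed=seed)
    foreign = spec.foreign
    if foreign is not None and spec.curate_foreign:
        if foreign_features is not None:
            raise ValueError(
                "cannot combine curate_foreign with precomputed foreign features; "
                "curate the corpus first and pass its own features"
            )
        foreign, _ = curate_corpus(foreign, spec.curation)
    if foreign is not None:
        clash = set(spec.local.doc_ids) & set(foreign.doc_ids)
        if clash:
            raise ValueError(f"local and foreign corpora share doc_ids: {sorted(clash)}")
    if local_features is None:
        local_features = featurize_corpus(spec.local, dictionary, lexicon, pos_provider, config)
    if foreign is not None and foreign_features is None:
        foreign_features = featurize_corpus(foreign, dictionary, lexicon, pos_provider, config)

    cells: list[CellScore] = []
    for r in range(plan.repeats):
        for f in range(plan.k):
            test_ids = plan.test_ids(r, f)
            train_ids = plan.train_ids(r, f)
            if spec.subset_size is not None:
                if spec.subset_size > len(train_ids):
                    raise ValueError(
                        f"subset size {spec.subset_size} exceeds training fraction "
                        f"of {len(train_ids)} documents"
                    )
                rng = np.random.default_rng([seed, 101, r, f])
                order = rng.permutation(len(train_ids))
                train_ids = [train_ids[i] for i in order[: spec.subset_size]]
            model_features = {i: local_features[i] for i in train_ids}
            if foreign is not None:
                model_features.update(foreign_features)
            leaked = set(test_ids) & set(model_features)
            if leaked:
                raise RuntimeError(f"test documents leaked into training: {sorted(leaked)}")
            evaluation = _evaluate_fold(
                model_features,
                [spec.local[i] for i in test_ids],
                local_features,
                config,
                seed,
            )
            _check_dominance(evaluation, f"repeat {r} fold {f}")
            cells.append(CellScore(repeat=r, fold=f, evaluation=evaluation))
    provenance = {
        "design": "cv",
        "local": spec.local.source_label,
        "foreign": foreign.source_label if foreign is not None else None,
        "curate_foreign": spec.curate_foreign,
        "subset_size": spec.subset_size,
        "k": plan.k,
        "repeats": plan.repeats,
        "plan_seed": plan.seed,
        "seed": seed,
    }
    return ExperimentResult(design="cv", cells=cells, provenance=provenance)


def run_cross_corpus(
    train_corpus: Corpus,
    test_corpus: Corpus,
    config: TaggerConfig | None = None,
    seed: int = 0,
    dictionary: TermDictionary | None = None,
    lexicon: BaseFormLexicon | None = None,
    pos_provider: POSProvider | None = None,
    allow_identical: bool = False,
) -> ExperimentResult:
    """Train on one whole corpus, test on another (both regimes)."""
    config = config or TaggerConfig()
    clash = set(train_corpus.doc_ids) & set(test_corpus.doc_ids)
    if clash and not allow_identical:
        raise ValueError(f"train and test corpora share doc_ids: {sorted(clash)}")
    train_features = featurize_corpus(train_corpus, dictionary, lexicon, pos_provider, config)
    test_features = featurize_corpus(test_corpus, dictionary, lexicon, pos_provider, config)
    evaluation = _evaluate_fold(
        dict(train_features), list(test_corpus), test_features, config, seed
    )
    _check_dominance(evaluation, "cross-corpus run")
    provenance = {
        "design": "cross_corpus",
        "train": train_corpus.source_label,
        "test": test_corpus.source_label,
        "seed": seed,
    }
    return ExperimentResult(
        design="cross_corpus",
        cells=[CellScore(repeat=0, fold=0, evaluation=evaluation)],
        provenance=provenance,
    )


@dataclass
class LearningCurveResult:
    """Three pooling arms evaluated across local training-subset sizes."""

    sizes: list[int]
    arms: dict[str, dict[int, ExperimentResult]]  # arm -> size -> result

    ARMS = ("local", "pooled", "pooled_curated")

    def mean(self, arm: str, size: int, mode: str = "exact", metric: str = "f1") -> float:
        return self.arms[arm][size].mean(mode, metric)

    def pooling_gain(self, mode: str = "exact", metric: str = "f1",
                     arm: str = "pooled") -> dict[int, float]:
        """Pooled-minus-local mean score per size."""
        return {
            s: self.mean(arm, s, mode, metric) - self.mean("local", s, mode, metric)
            for s in self.sizes
        }

    def majority_of_repeats(
        self,
        better: str,
        worse: str,
        mode: str = "exact",
        metric: str = "f1",
    ) -> dict[int, bool]:
        """Per size: does `better` beat-or-tie `worse` in most repeats?

        Repeat-level scores are fold means; the two arms share fold plans,
        so repeats are paired.
        """
        out = {}
        for s in self.sizes:
            a = self.arms[better][s].repeat_means(mode, metric)
            b = self.arms[worse][s].repeat_means(mode, metric)
            out[s] = int((a >= b - 1e-12).sum()) > len(a) / 2
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, by_size in self.arms.items():
            for size, result in by_size.items():
                for mode in ("exact", "overlap"):
                    rows.append(
                        {
                            "arm": arm,
                            "size": size,
                            "mode": mode,
                            "precision": result.mean(mode, "precision"),
                            "recall": result.mean(mode, "recall"),
                            "f1": result.mean(mode, "f1"),
                            "f1_std": result.std(mode, "f1"),
                        }
                    )
        return pd.DataFrame(rows)


def run_learning_curve(
    local: Corpus,
    foreign: Corpus,
    subset_sizes: Sequence[int],
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    config: TaggerConfig | None = None,
    dictionary: TermDictionary | None = None,
    lexicon: BaseFormLexicon | None = None,
    pos_provider: POSProvider | None = None,
    curation: CurationConfig | None = None,
) -> LearningCurveResult:
    """Local-only vs pooled vs curated-pooled CV across local subset sizes.

    All arms and sizes share one fold plan and one feature cache; subsets
    are nested across sizes within a (repeat, fold) cell, so arm and size
    comparisons are paired.
    """
    config = config or TaggerConfig()
    curation = curation or CurationConfig()
    sizes = sorted(set(int(s) for s in subset_sizes))
    plan = make_folds(local, k=k, repeats=repeats, seed=seed)
    min_train = min(len(plan.train_ids(r, f)) for r in range(repeats) for f in range(k))
    if sizes[-1] > min_train:
        raise ValueError(
            f"largest subset size {sizes[-1]} exceeds smallest training fraction {min_train}"
        )
    local_features = featurize_corpus(local, dictionary, lexicon, pos_provider, config)
    foreign_features = featurize_corpus(foreign, dictionary, lexicon, pos_provider, config)
    curated_foreign, _ = curate_corpus(foreign, curation)
    curated_features = featurize_corpus(
        curated_foreign, dictionary, lexicon, pos_provider, config
    )

    arm_setup = {
        "local": (None, None),
        "pooled": (foreign, foreign_features),
        "pooled_curated": (curated_foreign, curated_features),
    }
    arms: dict[str, dict[int, ExperimentResult]] = {arm: {} for arm in arm_setup}
    for size in sizes:
        for arm, (arm_foreign, arm_features) in arm_setup.items():
            spec = PoolingSpec(
                local=local, foreign=arm_foreign, curate_foreign=False,
                subset_size=size, curation=curation,
            )
            arms[arm][size] = run_cv(
                spec,
                plan=plan,
                config=config,
                seed=seed,
                local_features=local_features,
                foreign_features=arm_features,
            )
    return LearningCurveResult(sizes=sizes, arms=arms)
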