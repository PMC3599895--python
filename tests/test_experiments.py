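"""Fold plans, pooled cross-validation, cross-corpus transfer, learning curves."""

import numpy as np
import pytest

from corpuspool import (
    GuidelineProfile,
    PoolingSpec,
    SynthConfig,
    generate_corpus,
    make_folds,
    run_cross_corpus,
    run_cv,
    run_learning_curve,
)
from corpuspool.synthesis import inclusive_guideline, strict_guideline


@pytest.fixture(scope="module")
def cv_corpus(concept_lexicon):
    return generate_corpus(
        concept_lexicon, GuidelineProfile(), SynthConfig(n_docs=10, seed=31), "cv-local"
    )


class TestMakeFolds:
    def test_even_split(self, cv_corpus):
        plan = make_folds(cv_corpus, k=5, repeats=2, seed=0)
        for r in range(2):
            sizes = [len(plan.test_ids(r, f)) for f in range(5)]
            assert sizes == [2, 2, 2, 2, 2]
            assert sorted(sum((plan.test_ids(r, f) for f in range(5)), [])) == sorted(
                cv_corpus.doc_ids
            )

    def test_uneven_split_differs_by_at_most_one(self, concept_lexicon):
        corpus = generate_corpus(
            concept_lexicon, GuidelineProfile(), SynthConfig(n_docs=11, seed=32), "c11"
        )
        plan = make_folds(corpus, k=5, repeats=1, seed=0)
        sizes = sorted(len(plan.test_ids(0, f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_same_seed_same_plan(self, cv_corpus):
        assert make_folds(cv_corpus, seed=9) == make_folds(cv_corpus, seed=9)

    def test_too_few_documents(self, cv_corpus):
        with pytest.raises(ValueError, match="folds"):
            make_folds(cv_corpus, k=11)


@pytest.fixture(scope="module")
def cv_result(cv_corpus, term_dictionary, base_forms):
    plan = make_folds(cv_corpus, k=5, repeats=1, seed=1)
    return run_cv(
        PoolingSpec(local=cv_corpus),
        plan=plan,
        seed=1,
        dictionary=term_dictionary,
        lexicon=base_forms,
    )


class TestRunCv:
    def test_scores_are_probabilities_and_overlap_dominates(self, cv_result):
        frame = cv_result.to_frame()
        assert ((frame[["precision", "recall", "f1"]] >= 0).all().all())
        assert ((frame[["precision", "recall", "f1"]] <= 1).all().all())
        wide = frame.pivot_table(index=["repeat", "fold"], columns="mode", values="f1")
        assert (wide["overlap"] >= wide["exact"] - 1e-12).all()

    def test_cell_count_and_summary_shape(self, cv_result):
        assert len(cv_result.cells) == 5
        summary = cv_result.summary()
        assert set(summary.index) == {"exact", "overlap"}

    def test_mean_lies_within_cell_range(self, cv_result):
        values = cv_result.values("exact", "f1")
        assert values.min() <= cv_result.mean("exact", "f1") <= values.max()

    def test_determinism(self, cv_corpus, term_dictionary, base_forms, cv_result):
        plan = make_folds(cv_corpus, k=5, repeats=1, seed=1)
        again = run_cv(
            PoolingSpec(local=cv_corpus),
            plan=plan,
            seed=1,
            dictionary=term_dictionary,
            lexicon=base_forms,
        )
        assert again.to_frame().equals(cv_result.to_frame())

    def test_subset_larger_than_training_fraction_rejected(self, cv_corpus):
        plan = make_folds(cv_corpus, k=5, repeats=1, seed=1)
        with pytest.raises(ValueError, match="subset size"):
            run_cv(PoolingSpec(local=cv_corpus, subset_size=9), plan=plan, seed=1)

    def test_shared_doc_ids_with_foreign_rejected(self, cv_corpus):
        with pytest.raises(ValueError, match="share doc_ids"):
            run_cv(PoolingSpec(local=cv_corpus, foreign=cv_corpus), seed=1)


class TestCrossCorpus:
    def test_identical_corpora_need_explicit_flag(self, cv_corpus):
        with pytest.raises(ValueError, match="share doc_ids"):
            run_cross_corpus(cv_corpus, cv_corpus)

    def test_train_equals_test_is_near_ceiling(self, cv_corpus, term_dictionary, base_forms):
        result = run_cross_corpus(
            cv_corpus, cv_corpus, dictionary=term_dictionary, lexicon=base_forms,
            allow_identical=True,
        )
        assert result.mean("exact", "f1") >= 0.9

    def test_guideline_divergence_degrades_transfer(
        self, concept_lexicon, term_dictionary, base_forms
    ):
        cfg = dict(config=SynthConfig(n_docs=25, seed=41))
        same_a = generate_corpus(concept_lexicon, strict_guideline(), source_label="sa", **cfg)
        cfg_b = dict(config=SynthConfig(n_docs=25, seed=42))
        same_b = generate_corpus(concept_lexicon, strict_guideline(), source_label="sb", **cfg_b)
        divergent = generate_corpus(
            concept_lexicon,
            GuidelineProfile(p_article=0.4, p_possessive=0.1, p_merge_prep=0.5,
                             p_merge_conj=0.3, vocab_fraction=0.5),
            config=SynthConfig(n_docs=25, seed=43),
            source_label="div",
        )
        kw = dict(dictionary=term_dictionary, lexicon=base_forms, seed=0)
        compatible = run_cross_corpus(same_b, same_a, **kw).mean("exact", "f1")
        incompatible = run_cross_corpus(divergent, same_a, **kw).mean("exact", "f1")
        assert incompatible < compatible


@pytest.fixture(scope="module")
def small_curve(concept_lexicon, term_dictionary, base_forms):
    local = generate_corpus(
        concept_lexicon, strict_guideline(), SynthConfig(n_docs=10, seed=51), "lc-local"
    )
    foreign = generate_corpus(
        concept_lexicon, inclusive_guideline(), SynthConfig(n_docs=20, seed=52), "lc-foreign"
    )
    return run_learning_curve(
        local, foreign, subset_sizes=[2, 6], k=5, repeats=2, seed=3,
        dictionary=term_dictionary, lexicon=base_forms,
    )


class TestLearningCurve:
    def test_all_arms_and_sizes_present(self, small_curve):
        assert set(small_curve.arms) == {"local", "pooled", "pooled_curated"}
        for arm in small_curve.arms.values():
            assert sorted(arm) == [2, 6]
            for result in arm.values():
                assert len(result.cells) == 10  # 2 repeats x 5 folds

    def test_frame_has_both_modes(self, small_curve):
        frame = small_curve.to_frame()
        assert set(frame["mode"]) == {"exact", "overlap"}
        assert len(frame) == 3 * 2 * 2

    def test_pooling_gain_keys_match_sizes(self, small_curve):
        assert sorted(small_curve.pooling_gain()) == [2, 6]

    def test_oversized_subset_rejected(self, concept_lexicon, term_dictionary, base_forms):
        local = generate_corpus(
            concept_lexicon, strict_guideline(), SynthConfig(n_docs=10, seed=53), "l2"
        )
        foreign = generate_corpus(
            concept_lexicon, inclusive_guideline(), SynthConfig(n_docs=10, seed=54), "f2"
        )
        with pytest.raises(ValueError, match="subset size"):
            run_learning_curve(local, foreign, subset_sizes=[9], k=5, repeats=1, seed=0)
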