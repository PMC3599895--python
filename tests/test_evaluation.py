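"""Span pairing against an exhaustive oracle, PRF formulas, phrase overlap."""

import numpy as np
import pytest

from corpuspool import ConceptSpan, MatchResult, evaluate_corpus, pair_spans, phrase_overlap, prf
from corpuspool.evaluation import _compatible


def _spans(*ranges, line=0, t="problem"):
    return [ConceptSpan(line, s, e, t) for s, e in ranges]


class TestPairSpans:
    def test_exact_requires_both_boundaries(self):
        pred = _spans((1, 2), (5, 6))
        gold = _spans((1, 2), (4, 6))
        m = pair_spans(pred, gold, "exact")
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        m = pair_spans(pred, gold, "overlap")
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_identity_scores_perfectly(self):
        spans = _spans((0, 1), (3, 3), (5, 9))
        for mode in ("exact", "overlap"):
            m = pair_spans(spans, spans, mode)
            assert (m.fp, m.fn) == (0, 0)

    def test_empty_predictions(self):
        m = pair_spans([], _spans((0, 1), (2, 2)), "exact")
        assert (m.tp, m.fp, m.fn) == (0, 0, 2)

    def test_pairing_is_one_to_one(self):
        # one long prediction may claim only one of two gold spans
        pred = _spans((0, 9))
        gold = _spans((0, 1), (5, 6))
        m = pair_spans(pred, gold, "overlap")
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)

    def test_different_types_never_match(self):
        m = pair_spans(_spans((0, 1)), _spans((0, 1), t="treatment"), "overlap")
        assert m.tp == 0


def brute_force_max_pairing(pred, gold, mode):
    """Exhaustive maximum one-to-one pairing (independent oracle)."""
    if not pred:
        return 0
    head, rest = pred[0], pred[1:]
    best = brute_force_max_pairing(rest, gold, mode)
    for j, g in enumerate(gold):
        if _compatible(head, g, mode):
            best = max(
                best, 1 + brute_force_max_pairing(rest, gold[:j] + gold[j + 1 :], mode)
            )
    return best


def _random_spans(rng, n):
    out = []
    for _ in range(n):
        line = int(rng.integers(0, 2))
        s = int(rng.integers(0, 10))
        e = s + int(rng.integers(0, 4))
        out.append(ConceptSpan(line, s, e, "problem"))
    return out


@pytest.mark.parametrize("mode", ["exact", "overlap"])
def test_pairing_attains_exhaustive_maximum(mode):
    rng = np.random.default_rng(7)
    for _ in range(150):
        pred = _random_spans(rng, int(rng.integers(0, 7)))
        gold = _random_spans(rng, int(rng.integers(0, 7)))
        m = pair_spans(pred, gold, mode)
        assert m.tp == brute_force_max_pairing(pred, gold, mode)
        assert m.tp + m.fp == len(pred) and m.tp + m.fn == len(gold)


def test_overlap_dominates_exact_on_random_instances():
    rng = np.random.default_rng(8)
    for _ in range(100):
        pred = _random_spans(rng, int(rng.integers(0, 8)))
        gold = _random_spans(rng, int(rng.integers(0, 8)))
        exact, overlap = prf(pair_spans(pred, gold, "exact")), prf(
            pair_spans(pred, gold, "overlap")
        )
        assert overlap.precision >= exact.precision
        assert overlap.recall >= exact.recall
        assert overlap.f1 >= exact.f1


@pytest.mark.parametrize(
    ("tp", "fp", "fn", "p", "r", "f1"),
    [
        (1, 1, 1, 0.5, 0.5, 0.5),
        (0, 0, 5, 0.0, 0.0, 0.0),
        (3, 1, 0, 0.75, 1.0, 6 / 7),
        (0, 0, 0, 0.0, 0.0, 0.0),
        (0, 4, 0, 0.0, 0.0, 0.0),
        (10, 5, 2, 10 / 15, 10 / 12, 2 * (10 / 15) * (10 / 12) / (10 / 15 + 10 / 12)),
    ],
)
def test_prf_formulas_and_zero_conventions(tp, fp, fn, p, r, f1):
    score = prf(MatchResult("exact", tp, fp, fn))
    assert score.precision == pytest.approx(p)
    assert score.recall == pytest.approx(r)
    assert score.f1 == pytest.approx(f1)


class TestEvaluateCorpus:
    def test_counts_pool_before_ratios(self):
        doc1 = (_spans((0, 1), (4, 4)), _spans((0, 1), (6, 6)))  # tp=1 fp=1 fn=1
        doc2 = (_spans((2, 3), (8, 9)), _spans((2, 3), (8, 9)))  # tp=2
        ev = evaluate_corpus({"a": doc1[0], "b": doc2[0]}, {"a": doc1[1], "b": doc2[1]})
        assert ev.exact.precision == pytest.approx(0.75)
        assert ev.exact.recall == pytest.approx(0.75)

    def test_all_empty_predictions_give_zero_recall(self):
        ev = evaluate_corpus({"a": []}, {"a": _spans((0, 1))})
        assert ev.exact.recall == 0.0 and ev.overlap.recall == 0.0

    def test_single_document_equals_pair_spans(self):
        pred, gold = _spans((0, 1), (3, 4)), _spans((0, 2), (3, 4))
        ev = evaluate_corpus({"a": pred}, {"a": gold})
        assert ev.exact_counts == pair_spans(pred, gold, "exact")

    def test_document_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="gold-only=\\['b'\\]"):
            evaluate_corpus({"a": []}, {"a": [], "b": []})


class TestPhraseOverlap:
    def test_ignoring_one_start_word_bridges_article(self):
        src = [("severe", "cough")]
        tgt = [("the", "severe", "cough")]
        assert phrase_overlap(src, tgt, "exact").fraction == 0.0
        assert phrase_overlap(src, tgt, "ignore_one_start_word").fraction == 1.0

    def test_identical_sets_fully_overlap_in_all_modes(self):
        phrases = [("chest", "pain"), ("fever",)]
        for mode in ("exact", "ignore_one_start_word", "ignore_one_word"):
            assert phrase_overlap(phrases, phrases, mode).fraction == 1.0

    def test_interior_word_needs_ignore_one_word(self):
        src = [("pain", "in", "chest")]
        tgt = [("pain", "chest")]
        assert phrase_overlap(src, tgt, "ignore_one_start_word").fraction == 0.0
        assert phrase_overlap(src, tgt, "ignore_one_word").fraction == 1.0

    def test_single_word_phrases_are_never_deleted_from(self):
        assert phrase_overlap([("fever",)], [("cough",)], "ignore_one_word").fraction == 0.0

    def test_source_multiset_counts_occurrences(self):
        stats = phrase_overlap([("fever",), ("fever",), ("rash",)], [("fever",)], "exact")
        assert (stats.n_source, stats.n_matched) == (3, 2)
        assert stats.fraction == pytest.approx(2 / 3)

    def test_empty_source_is_an_error(self):
        with pytest.raises(ValueError, match="empty source"):
            phrase_overlap([], [("fever",)], "exact")

    def test_matches_brute_force_deletion_oracle(self):
        rng = np.random.default_rng(11)
        vocab = ["a", "b", "c", "d"]

        def rand_phrases(n):
            return [
                tuple(rng.choice(vocab, size=rng.integers(1, 4))) for _ in range(n)
            ]

        def oracle(src, tgt, mode):
            def variants(p):
                vs = {p}
                if len(p) >= 2 and mode == "ignore_one_start_word":
                    vs.add(p[1:])
                if len(p) >= 2 and mode == "ignore_one_word":
                    vs |= {p[:i] + p[i + 1 :] for i in range(len(p))}
                return vs

            hits = 0
            for s in src:
                if any(variants(s) & variants(t) for t in set(tgt)):
                    hits += 1
            return hits

        for _ in range(60):
            src, tgt = rand_phrases(int(rng.integers(1, 8))), rand_phrases(int(rng.integers(1, 8)))
            for mode in ("exact", "ignore_one_start_word", "ignore_one_word"):
                assert phrase_overlap(src, tgt, mode).n_matched == oracle(src, tgt, mode)
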