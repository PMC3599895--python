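# Methods

This note documents the models, conventions and numerical choices behind
`corpuspool`, in the order data flows through the package.

## Corpus representation and tokenization

A document is a sequence of sentence lines; a line is a sequence of
whitespace-free tokens; a concept annotation is a `(line, start_token,
end_token)` triple with inclusive end, a semantic type (here always
`problem`), and an informational surface string re-derived from the
tokens. Internally everything is 0-based; the serialized standoff format
uses 1-based line numbers and 0-based token offsets, the common
convention of i2b2-style `.con` records. Concepts are confined to a
single line; multi-line records are rejected at read time with a
diagnostic rather than an error, as are out-of-bounds and malformed
records, so one bad record never discards a document.

The tokenizer splits on whitespace and then peels leading/trailing
punctuation characters into their own tokens, keeping internal
punctuation ("chest-pain", "x-ray" stay whole). This rule is a package
choice — corpus token counts alone cannot pin down any particular
tokenizer — and the same tokenizer is used for corpus reading,
dictionary terms and the generator, so offsets always agree.

## Normalization and dictionary lookup

Tokens are normalized for dictionary matching by, in order: lowercasing,
removing Unicode-punctuation characters, mapping Greek-block letters to
the marker `G` and digits to `9`, then replacing the result by a base
form from a surface→lemma lexicon when present. Lexicon keys and values
are themselves normalized at load and value chains are resolved to their
terminal form, so the full normalization is a projection (idempotent) on
any Greek-free input. The Greek marker is deliberately the uppercase
letter `G` (the established dictionary convention); feeding an already
normalized Greek-bearing token through again would lowercase the marker.
Normalization is applied exactly once per token in the pipeline, so this
never arises in practice; the property test therefore checks idempotence
over a Greek-free alphabet and the Greek mapping separately.

Lookup reports **every** dictionary phrase occurrence — nested and
overlapping matches included — because the match state is a feature, not
a prediction. Windows run over tokens whose normalized form is non-empty:
pure punctuation tokens are transparent, so a phrase may span an internal
comma, and reported spans always begin and end on content tokens. The
production lookup indexes entries by first token; its contract is
equality with the brute-force all-windows oracle, which the suite checks
on 500 random instances.

## Features and the sequence tagger

Concept extraction is BIO sequence labeling per line. Each token carries
lexical features (word, lowercased word, prefixes and suffixes of length
1–4), orthographic features (character shape `Aa9-`, run-compressed
shape, digit flag), a POS tag, and the dictionary-match state (`B-`/`I-`
per label of the longest covering match, ties broken leftmost). The same
inventory is repeated at offsets −2..+2 — the five-token window — with
BOS/EOS sentinels beyond the line. POS tags come from a pluggable
provider; the built-in provider is a deterministic closed-class +
suffix-rule tagger (default `NN`), and POS features can be disabled
entirely.

The tagger is a linear-chain model: a multinomial logistic-regression
(maximum-entropy) emission model over feature-hashed inputs (2^16
dimensions, signed hashing), combined with label-bigram transition
log-probabilities estimated from the training corpus with add-one
smoothing, decoded by Viterbi. `I` after `O` or at line start is a
structural zero, so decoded sequences are always valid BIO; the decoder
for externally supplied label files is tolerant instead (a stray `I`
opens a span) and documents that repair rule. The solver (lbfgs,
C = 1.0, 100 iterations, tol 1e-4) is deterministic for fixed data and
seed, which makes whole experiments reproducible. Hash dimension,
regularization and iteration cap were fixed once as a speed/accuracy
compromise adequate for corpora of a few thousand lines; they are stored
in the model metadata, and a model always predicts with the feature
configuration, dictionary and lexicon it was trained with.

A dictionary-only baseline (longest non-overlapping lookup matches) is
provided as the reference that the learned tagger must beat on held-out
data — the learner must add value over its own feature source.

## Evaluation

Predicted and gold spans are paired one-to-one: the score derives from a
*maximum* bipartite pairing (augmenting-path matching) under the match
predicate — exact boundary equality, or any token overlap. One-to-one
pairing means a single long prediction cannot claim several gold spans;
the overlap regime's edge set contains the exact regime's, so overlap
P/R/F1 dominate exact P/R/F1 cell by cell, and every experiment run
asserts this invariant. Corpus scores are micro-averaged: counts are
summed over documents before ratios, the usual challenge convention.
Zero denominators yield 0 for the affected measure.

Phrase-overlap statistics compare annotation surface vocabularies of two
corpora, case-insensitively on raw (not normalized) tokens, since they
diagnose guideline differences in what annotators marked: a source
phrase (occurrence-counted) matches exactly, or after deleting the first
word from either side, or after deleting any single word from either
side; deletions apply only to phrases of length ≥ 2.

## Curation

Guideline reconciliation strips leading articles
(`a, the, any, some, an, this`) and possessive pronouns (`his, her`)
from annotation starts, iteratively, never emptying a span and never
touching interior words ("removal of the mass" is unchanged) — matching
what can be automated cheaply; prepositional-phrase and conjunction
differences are deliberately left uncorrected so their effect stays
measurable. Duplicates created when two spans collapse onto the same
phrase are removed. The operation is idempotent, and for generated
corpora it is exactly invertible in distribution: curating a corpus
generated with inclusion probabilities `(p_article, p_possessive)`
reproduces the annotation phrase multiset of the seed-matched
zero-probability corpus exactly (see the generator contract below).

## Synthetic corpora

The generator is template-based, not a language model: templates give
exact control over gold spans, which is what guideline experiments need.
Documents mix filler sentences (including decoy contexts like "the
patient reports gradual improvement", so context alone cannot identify
concepts) with concept-bearing sentences of four kinds: plain mentions,
non-patient mentions ("referred to the <disease> department"),
concept + prepositional phrase ("pain in the chest"), and conjunction
lists. The concept lexicon holds ~180 one- to four-token problem
phrases built from symptom, site, condition and modifier inventories,
disjoint from the filler vocabulary.

A `GuidelineProfile` controls: the probability that an annotation is
extended over an inserted preceding article (default rate in the
inclusive profile: 0.11, articles drawn with the frequencies observed in
problem-annotated challenge data) or possessive pronoun (0.03); whether
non-patient mentions are annotated; merge probabilities for
prepositional and conjunction patterns (the inclusive profile uses 0.8
and 0.5 — order-of-magnitude choices, since no measured prevalence
exists); and the fraction of the master lexicon the corpus draws on
(default 0.8 per side, drawn independently, so roughly 80% of one side's
vocabulary is known to the other).

Two structural guarantees matter for the tests. First, every stochastic
decision consumes random draws in a fixed order that does not depend on
the profile's probability values (draw-then-threshold), so seed-matched
corpora differing only in probabilities share their underlying concept
stream. Second, article/possessive inclusion *inserts* the stop word,
leaving the base phrase intact, which is what makes curation recovery
exact. Token-level concept density is steered toward the target (default
0.11) by a corpus-level controller that counts only profile-independent
base tokens; the generator raises an error if the realized density
strays more than 0.03 from the target. Line lengths emerge from the
templates (~7.5 tokens on average) rather than from a config knob.

What the generator does **not** emulate: real clinical language and its
misspellings, abbreviations, section structure, de-identification
artifacts, report-type-specific terminology shifts (report types only
re-weight templates slightly), and concept-definition scope differences
between guidelines. Passing experiments therefore demonstrate that the
pipeline and designs behave correctly and that guideline mechanics have
the expected directional effects — not that any particular F1 level
would be attained on real notes.

## Experimental designs and problem sizes

Cross-validation uses seeded shuffle + round-robin folds (sizes differ
by at most one). Pooling adds the foreign corpus whole to every training
fold — supplementation, never sampling — while subset truncation applies
only to the local training fraction, with subsets nested across sizes
within a cell so size comparisons are paired. Full-corpus CV defaults to
3 repeats and subset curves to 5 repeats of 5-fold CV, the extra repeats
compensating for the higher variance of small subsets. Aggregates are
means (with standard deviations) over repeat × fold cells of
micro-averaged scores. A leakage guard raises if any test document
reaches a training set.

The default study conditions are: local corpus of 30 documents under the
strict guideline, foreign corpus of 120 documents (4× local) under the
inclusive guideline, subset grid {3, 6, 12, 24} (geometric; 24 is the
full training fraction). These sizes keep the full battery — about 300
tagger trainings — to a few minutes on one CPU while leaving the
qualitative phenomena clearly resolved.

One measurement choice deserves emphasis: the finding "pooling increases
recall" is assessed on **overlap**-mode recall. Exact-mode recall
confounds concept recognition with span-extent convention — a pooled
model that finds every concept but extends spans the foreign way scores
zero exact recall on those mentions. Overlap recall isolates
recognition, which is the quantity pooling is supposed to improve; the
exact-mode numbers are reported alongside and do show pooled recall
falling below local-only at the largest subset size, consistent with the
precision/boundary cost of guideline divergence.

## Known limitations

- The sequence model factorizes emission and transition scores
  (maximum-entropy + bigram Viterbi) rather than training them jointly;
  this is a modeling choice adequate for the short, template-like lines
  generated here.
- Concepts may not span lines, and the CoNLL path cannot represent
  overlapping gold spans (lookup matches may overlap; gold spans of one
  type must not).
- The phrase-overlap leniency modes compare single-word deletions only;
  two-word differences count as mismatches in every mode.
- Synthetic-corpus results transfer qualitatively, not numerically, to
  real clinical text (see generator caveats above).
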