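# Methods

## Problem setting

`chemtriage` implements binary document classification for literature triage:
given a labeled corpus of titles and abstracts (positive = "corpus-like",
e.g. medicinal-chemistry papers of the kind curated into a bioactivity
database; negative = a random bibliographic background of the same size), it
learns a scoring function used to rank, filter and gate new documents before
manual curation. Only the title and abstract are used — no full text, author,
journal or citation metadata.

## Preprocessing pipeline

Order of operations, applied to the title stream and then the abstract
stream:

1. **Punctuation removal** — every character outside `[a-z0-9]` (after
   lowercasing) becomes a space; hyphens and underscores therefore split
   words. This is the simplest rule consistent with the worked tokenization
   example; chemistry tokens fragment identically in both classes, so the
   fragmentation is class-neutral.
2. **Lowercasing**, then splitting on whitespace.
3. **Stop-word removal** against a configurable list. The default is a
   standard ~130-word SMART-derived English list
   (`chemtriage.preprocess.DEFAULT_STOP_WORDS`); any project list can be
   supplied as a plain-text file.
4. **Porter stemming** (classic 1980 algorithm, implemented in
   `chemtriage._porter` and tested against the algorithm's canonical
   input/output pairs). The stemmer used by the workflow this package
   modernizes is closed-source and does not match any public stemmer on every
   example token; the two tokens where its printed output differs from
   classic Porter (`discover`/`discoveri`, `large`/`larg`) are recorded in a
   machine-readable variant map (`PRINTED_STEM_VARIANTS`) so worked examples
   can be checked modulo that map. Reproducibility with a published algorithm
   was preferred over mimicry of a closed one.
5. **Short-token removal** — stemmed tokens shorter than `min_token_length`
   (default 4, i.e. length ≤ 3 dropped) are removed. The length test runs on
   the *stemmed* token, consistent with 5-letter stems surviving while
   3-letter raw words do not. Pure-digit tokens get no special casing: they
   survive iff ≥ 4 digits.

**N-grams** (orders 2 and 3 by default) are built from the *unstemmed*,
lowercased, punctuation-stripped word stream with stop words kept, joined by
`_`. Title and abstract are windowed separately, so no n-gram spans the
boundary. A stream of L words yields max(0, L−n+1) n-grams. N-gram and
unigram features live in one vocabulary, each tagged with a namespace, so the
n-gram configuration is a strict superset of plain BoW.

## Vectorization

A document is encoded as a binary presence/absence row over the vocabulary.
Term order is first occurrence across the training stream (never
lexicographic), which makes small worked examples reproducible bit-for-bit.
`min_doc_freq` (default 1 = no cutoff) can drop rare terms on real corpora.
Tokens outside the trained vocabulary are silently ignored at scoring time —
new literature always contains unseen terms.

## Classifiers

**Naive Bayes (default, `laplace_relative`).** Per-feature weight
`w_f = ln[(A_f+1)/(B_f·p+1)]` where `A_f` counts positive training documents
containing `f`, `B_f` all training documents containing `f`, and `p` is the
prior positive fraction (default: empirical). The document score is the sum
of present-feature weights; absence contributes nothing. The weight is
exactly 0 when `A_f = B_f·p`, positive for over-represented features, and
bounded above by `ln(1/p)`. A full Bernoulli NB (Laplace α = 1, absence terms
folded into per-feature weights plus an intercept) is available with
`variant="bernoulli"`; it is cross-checked against scikit-learn's
`BernoulliNB` in the test suite.

**Decision threshold.** The MCC-maximizing cut on the *training* scores
(candidates = observed scores; ties resolved to the lowest threshold;
degenerate inputs fall back to 0). Ranking use cases ignore the threshold.
Known limitation: with singleton-rich vocabularies (n-grams at
`min_doc_freq=1`) training scores are inflated by features that occur in a
single training document, so the training-derived threshold does not transfer
to new data even though the *ranking* (AUC) is unaffected. For thresholded
classification with n-grams, raise `min_doc_freq` or set the threshold on a
validation split.

**Random forest.** Bagged CART trees over the binary features: each tree is
grown on a bootstrap sample of the training-set size, drawing
⌈√|vocabulary|⌉ candidate features per split and choosing by Gini impurity
decrease, no depth cap, 100 trees by default. Individual trees are grown by
scikit-learn's `DecisionTreeClassifier`; bootstrap sampling, out-of-bag
accounting, the JSON-serializable tree representation and prediction
traversal are implemented in-package. All randomness flows from one explicit
seed, so a fixed seed yields a bit-identical forest; there is no global
random state anywhere in the package. The out-of-bag score of a training
document is its mean positive-vote fraction over the trees whose bootstrap
excluded it (NaN if it was in every bag); the default class cut on vote
fractions is 0.5.

**Feature importance.** Two schemes: (i) the signed NB weight per term
(positive association ⇔ positive weight; a weight of exactly 0 is reported as
negative and is distinguishable by its zero magnitude); (ii) the number of
internal nodes within the first `max_level` (default 3) levels of every tree
that split on the term, with a per-level breakdown. The level-1 count tracks
Gini importance, but only when the informative features are few and dominant:
under √p candidate sampling the root-split frequency of the k-th strongest
feature is proportional to the probability that no stronger feature is in the
candidate draw, which separates adjacent strength ranks by only ~2% relative
when many features have similar strength. With ~60 comparable class-specific
terms the top-5 boundary of the level-1 ranking is therefore statistically
unresolvable at any practical forest size; the correlation test uses a
corpus with 3 class-specific terms per class and 500 trees, where both
rankings concentrate on the same six features.

## Evaluation

* **Stratified split**: per class, `round(class_size · test_fraction)`
  documents to the test side after a seeded within-class shuffle.
* **Sensitivity / specificity**: `TP/(TP+FN)`, `TN/(TN+FP)`; reported as NaN
  (never 0) when a denominator is empty.
* **MCC**: `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, with the
  documented convention MCC = 0 when any marginal factor is 0.
* **AUC**: tie-aware rank (Mann–Whitney) statistic — the probability that a
  random positive outscores a random negative, ties counted ½ — exactly equal
  to trapezoidal integration of the tie-aware ROC. The ROC curve sweeps every
  distinct score threshold and runs from (0,0) to (1,1).
* **Top-k% analysis**: documents ranked by descending score with doc_id as
  deterministic tie-break; the slice size is `floor(fraction · N)`; reported
  as (slice size, false positives, true positives).

## Synthetic corpus generator

The generator (`chemtriage.synth`) emulates the structure of a curated
corpus vs. random background: two classes share a Zipf-distributed common
vocabulary (exponent 1.1), and each class owns a set of class-specific terms
that occur only in its own documents, interleaved at evenly spaced ranks
through the frequency spectrum (so some are common, some rare) and
over-sampled by `discriminative_boost`. Defaults — the package's standard
study conditions, used by the acceptance tests — are 2,000 documents per
class, a 2,000-term shared vocabulary, 30 class-specific terms per class
boosted 5×, 12-word titles and 150-word abstracts (Poisson lengths, titles
floored at 3 words), and one stop word per four tokens from a fixed 8-word
list. Content words are pronounceable CVCV strings of ≥ 4 characters, so they
survive the preprocessing filters; dedicated fixtures with real stop/short
words exercise the filters instead.

`expected_term_stats` returns analytic per-class expected document
frequencies via Poisson thinning, `E[df] = n·(1 − exp(−λ·(1−ρ)·p))` with λ
the mean total length, ρ the stop-word rate and p the per-token probability;
the 3-word title floor biases this by < 0.1% at the default title mean. The
empirical frequencies from the vectorizer are checked against 4σ binomial
bands in the tests.

What the generator does **not** emulate: word co-occurrence and syntax,
within-document burstiness (words are i.i.d. given the class), correlation of
document length with class, vocabulary drift over time, journal/date
metadata. Tests passing on this generator demonstrate that the statistical
machinery is correct and that the pipeline recovers planted structure — not
that real corpora are as separable as the synthetic ones.

## Problem sizes and determinism

The test suite and acceptance checks run at desk scale: 4,000-document
corpora for the holdout/OOB/importance/n-gram checks, 1,000–5,000 documents
for generator calibration checks, 100 random instances of n ≤ 200 for
metric-oracle agreement. Every stochastic operation takes an explicit seed;
identical config + seed reproduces every output file byte-for-byte (model
files contain no timestamps).

## Design choices on open points

* Structured MEDLINE abstracts are flattened by joining `AbstractText`
  sections with single spaces, discarding labels; records with a missing
  title are skipped with a logged warning.
* TSV corpus files forbid embedded tabs/newlines (validation error); JSONL is
  the lossless interchange format.
* Keyword filtering defaults to whole-word matching (multi-word keywords
  match as adjacent word sequences); substring matching is an explicit flag,
  so "malaria" ≠ "antimalarial" surprises are never silent.
* The dictionary gate counts token *occurrences* (≥ `min_count`, default 5)
  rather than distinct terms, with a `types` mode available; matching is
  stemmed when the pipeline stems, so inflected forms count.
* Cost accounting treats the keyword-matched set as the set a curator would
  otherwise read: `n_before` = keyword matches, `n_after` = classifier
  positives, saving = `(n_before − n_after) · cost_per_article` (default $30).
* In the gated workflow the majority class of the labeled seed set is
  downsampled (seeded) before NB training, so both classes contribute
  equally.
* NB scores are not normalized by document length; longer documents can
  accumulate larger-magnitude scores. This matters for thresholding across
  heterogeneous collections, not for ranking within one.

## Known limitations

* The NB threshold overfits on vocabularies dominated by document-unique
  features (see above).
* The forest tie-break between equally good splits is whatever the
  underlying CART implementation does at the given seed; it is deterministic
  per seed but not the "lowest feature index" rule.
* `score_feed_item` and the CLI provide scoring hooks only; feed polling,
  posting and storage are out of scope.
* No probability calibration; NB scores are log-ratio-like quantities, not
  probabilities.
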