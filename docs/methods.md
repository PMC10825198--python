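# Methods

This note documents the models and procedures implemented in `ezloc`, the
choices made where the design was genuinely open, and what the synthetic
corpus does and does not establish.

## Text normalization

Cleaning applies its sub-steps in a fixed order: bracketed spans `() [] {}`
are deleted first (so later punctuation stripping cannot orphan a
delimiter), then any whitespace-delimited token containing a decimal digit
is deleted whole (dates, times, electrode names such as `B2`), remaining
punctuation becomes whitespace, clinical abbreviations are expanded at word
boundaries case-insensitively, and the result is lowercased with collapsed
whitespace. Deleting the *whole* digit-bearing token (rather than only the
digit characters) was chosen because the artefacts being removed are
patterns, not words with incidental digits; diacritics are preserved
(Italian text). Cleaning is idempotent, which requires that abbreviation
expansions contain no digits, punctuation or further abbreviations — the
shipped resource files satisfy this and custom resources must too.

Lemmatization is a dictionary lookup with identity fallback. A production
deployment would plug in a full Italian tagger; the resource-file design
keeps the pipeline runnable and testable without one, at the cost of
leaving unknown inflections unlemmatized (character n-grams absorb part of
that, which is their purpose). The stop-list is a plain-text resource with
~100 Italian closed-class words.

The 20-token exclusion threshold is measured after cleaning and
tokenization but **before** stop-word removal. Previous-seizure references
are detected by lemma co-occurrence patterns (default: `simile` and
`precedente` in one document) — in clinical practice this exclusion is
editorial, so every exclusion is listed in the filter report for review. A
document failing both checks is counted once, as short.

## Bag of words (*bw*)

Character n-grams (n = 2, 3) are extracted within tokens and never cross a
word boundary; word n-grams span n = 1..4. The feature budget splits 20/80
between the groups (exact for 100/200/300 features; rounding is
half-away-from-zero otherwise). "Most frequent" means raw corpus term
count on the training documents only, with lexicographic tie-breaking so a
fit is a deterministic function of its input. Counts stay raw in the
representation; scaling is the experiment runner's fold-local
standardization step. If a corpus supplies fewer candidates than a budget,
all candidates are kept and a shortfall warning is logged.

## Word embedding

Skip-gram with negative sampling, implemented in vectorized numpy:

* defaults D = 100, 10 negatives, window 3 (dynamic per position, as in
  word2vec), min count 2, 300 epochs, learning rate decaying linearly
  0.025 → 1e-4, noise distribution ∝ unigram^0.75;
* CBOW is available behind `algorithm="cbow"`; skip-gram is the default
  because it behaves better on small corpora;
* the input matrix is initialized uniform ±0.5/D, the output matrix at
  zero; training is single-threaded and deterministic given (corpus,
  params, seed);
* two departures from classic word2vec, both for speed and stability on
  desk-scale corpora: negatives are shared across a mini-batch (the
  negative pass becomes two GEMMs), and scatter updates average — rather
  than sum — the within-batch gradients of a row. Summed updates diverge on
  small vocabularies where one frequent word recurs hundreds of times per
  batch; averaging bounds every row's step by the learning rate. Tests
  confirm the learned geometry (planted co-occurrence similarity, planted
  additive analogy structure) survives these choices.

The training corpus is the learning-set seizure descriptions plus
unlabeled EMR excerpts; EMR text enters only here. The embedding is trained
once per learning set, not per CV fold — a deliberate, documented source of
mild optimism shared by the protocol it implements (fold-local retraining
is available by passing a custom representation factory).

Document pooling: *mean* averages in-vocabulary token vectors with
multiplicity; *tfidf* weights distinct terms by tf·idf with the smoothed
idf `ln((1+N)/(1+df)) + 1` (N learning-set documents) and normalizes by the
total weight, so a document with one distinct term returns that term's
vector exactly. Unseen terms at transform time get the df = 0 idf.
Out-of-vocabulary tokens are skipped; an all-OOV document maps to the zero
vector with a logged warning instead of an error, so held-out transforms
never fail.

## Intrinsic evaluators

Word similarity is cosine, clamped to [−1, 1] against rounding; zero-norm
vectors are an error. Analogies use 3CosAdd with the three query words
excluded from the candidates (the additive form matches the worked
"arm + leg − foot = hand" style of query; 3CosMul is a known alternative).
The outlier of a word group is the member with the lowest mean cosine to
the others. All ties break lexicographically, making reports reproducible.
The published Italian neighbour/outlier tables depend on a privately
trained model, so they are encoded here as report formats and as
planted-geometry tests, not as expected outputs.

## Experiment protocol

Patients are split before anything is fitted; `split_by_patient` resamples
(bounded attempts) until every class of every requested task appears on
both sides. Within the learning set, cross-validation stratifies over
seizure documents, treating seizures as independent events — one patient's
seizures may land in different folds; this follows the protocol being
implemented, and a patient-grouped CV can be had by splitting with
`split_by_patient` at fold level instead. The inner 10-fold grid search
maximizes weighted F1 (the headline metric); ties keep the first grid
entry. Hyperparameter grids (log-spaced, configurable): C ∈
{0.01, 0.1, 1, 10, 100} for all models, RBF γ ∈ {scale, 1e-3, 1e-2, 1e-1,
1}, polynomial degree fixed at 3. "Data normalization" is per-feature
centering/scaling fitted on the training portion and applied to all
representations, counts included. Solvers are bounded (liblinear tol 1e-2,
SVC iteration cap) so that pathological no-signal folds terminate; on
separable data the bounds are inactive.

Weighted metrics: for each class c with support share w_c, the per-class
value (treating c as positive) enters as w_c·m_c; a zero-denominator ratio
contributes 0 and the fold record is flagged. This makes single-class test
folds well-defined rather than errors. Aggregation: per-repetition median
across folds, then mean ± sd across the three repetitions; confusion counts
are summed across folds and averaged across repetitions.

## Synthetic corpus

The generator emulates the statistical shape of a private clinical corpus:

* 122 patients by default; seizures per patient follow a negative binomial
  truncated to [1, 17] with (r, μ) moment-matched by grid search so the
  truncated distribution has mean ≈ 4.39 and sd ≈ 3.63;
* labels live at the patient level with prevalences 60/122 left, 59/122
  temporal, and 29/49 frontal among extra-temporal patients;
* each class owns a disjoint set of invented Italian-flavored marker
  lemmas; a document receives Binomial(8, π) markers of its class per task.
  π = 0 therefore means markers never appear and the text is independent of
  the labels; π defaults to 0.6 ("moderate signal") for demonstrations;
* eight clinician style profiles perturb the Zipf-weighted background
  lemma distribution (lognormal multipliers), typical document length and
  function-word rate;
* raw-text noise rates (per document: dates 0.4, brackets 0.3, electrodes
  0.25, abbreviations 0.5; per token: misspellings 0.02) are Bernoulli
  draws whose realized counts are recorded in the ground truth;
* EMR documents are 5–20× longer, function-word heavy, share the
  background vocabulary and contain no marker lemmas (emulating the
  upstream removal of conclusion sections that would reveal the EZ).

What a green test establishes: the pipeline recovers planted lexical
signal, is calibrated (chance at π = 0, monotone response, saturation at
high π), leaks nothing from holdout patients, and reproduces bit-exactly
under fixed seeds. What it does not establish: clinical validity. The
generator's prose is nonsense; real semiology signal is distributed,
correlated and far subtler than disjoint marker sets, so published
performance levels on clinical text are not reproduced — by design the
published headline numbers are unattainable at desk scale and are treated
as protocol, not targets.

## Numerical conventions

* Rounding of the char-n-gram budget: half away from zero.
* All ranking ties (n-grams, vocabulary order, similarity, analogy,
  outlier): lexicographic.
* Idf of a term unseen at fit time: `ln(1+N) + 1`.
* Degenerate documents (empty after cleaning, all OOV): zero feature
  row / zero vector, logged, never an exception.
* Metric ratios with zero denominator: contribute 0, flagged in the fold
  record.
* Seeds: corpus generation, embedding init/negatives and CV shuffling are
  all `numpy` `default_rng` streams keyed by explicit integer seeds; reruns
  are bit-identical (liblinear gets a fixed `random_state`).

## Known limitations

* The lemma lexicon is small; unknown inflections pass through unchanged.
* The embedding trainer targets desk-scale corpora (≤ a few MB of text);
  it is not a replacement for a production word2vec on large corpora.
* Weighted NPV/specificity for heavily imbalanced folds can be dominated
  by the majority class — inherent to support weighting.
* The generator does not model label noise, inter-rater disagreement, or
  correlated markers across tasks.
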