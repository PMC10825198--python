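# ezloc

Localizing the epileptogenic zone (EZ) from free-text seizure semiology.

In the pre-surgical work-up of drug-resistant focal epilepsy, expert
epileptologists review video-EEG recordings and write short free-text
descriptions of each seizure's semiology. Those descriptions carry localizing
information about the EZ — the brain region whose removal abolishes seizures —
but reading them reliably takes years of experience. `ezloc` implements a
clinical-NLP pipeline that turns such descriptions into numerical
representations and trains shallow classifiers for three binary questions:

* **side** — left vs right hemisphere (positive class *left*);
* **localization** — temporal vs extra-temporal (positive class
  *extra-temporal*);
* **sublocalization** — within extra-temporal patients, frontal vs posterior
  (positive class *posterior*).

Real corpora of this kind are private clinical data, so the package ships a
synthetic-corpus generator with the same statistical structure
(patient-grouped documents, class-conditional marker vocabulary with tunable
signal strength π, clinician style variability, raw-text noise such as dates,
electrode names, bracketed annotations, abbreviations and misspellings).
Every stage of the pipeline is tested against that generator's ground truth.

## Method

1. **Preprocessing.** Cleaning (bracketed spans, digit-bearing tokens such as
   `14:30` or `B2`, punctuation; clinical abbreviations expanded, e.g.
   `aass → arti superiori`), whitespace tokenization, dictionary
   lemmatization with identity fallback, stop-word removal. Two corpus
   filters exclude descriptions shorter than 20 tokens (after cleaning) and
   descriptions that merely refer to previous seizures.
2. **Representations.**
   * *bw* — mixed n-gram bag of words: 20% character n-grams (n = 2, 3,
     within tokens; robust to misspellings) and 80% word n-grams (n = 1..4),
     ranked by learning-set frequency, total features ∈ {100, 200, 300};
   * *mean* — document vector `v_d = (1/|d|) Σ_{w∈d} v_w` over in-vocabulary
     tokens of a word2vec skip-gram/negative-sampling embedding (D = 100,
     10 negatives, window 3, min count 2, 300 epochs) trained on the
     learning-set seizure descriptions plus unlabeled EMR excerpts;
   * *tfidf* — `v_d = Σ_t tf(t,d)·idf(t)·v_t / Σ_t tf(t,d)·idf(t)` with the
     smoothed `idf(t) = ln((1+N)/(1+df(t))) + 1`.
3. **Intrinsic embedding evaluation** before any pooling: cosine word
   similarity, word analogies solved with 3CosAdd
   (`argmax_x cos(v_x, v_{a*} − v_a + v_b)`), and outlier detection (lowest
   mean cosine to the group).
4. **Evaluation protocol.** Patients (never individual seizures) are split
   into a learning and a holdout set. On the learning set: stratified outer
   10-fold CV over seizure documents, inner 10-fold grid search maximizing
   weighted F1, per-feature standardization and representation fitting local
   to each training fold, N = 3 repetitions with shuffling seed equal to the
   repetition index. Models: sparse logistic regression (L1) and SVMs with
   linear, RBF and degree-3 polynomial kernels. Metrics are class-support
   weighted: accuracy, precision, NPV, specificity, F1; the headline number
   is the mean ± sd over repetitions of the per-repetition median across
   folds. The holdout set is touched once, at the end, with leakage guarded
   by digests of every fitted object.

## Worked example

`python examples/05_nested_cv.py` — synthetic corpus, 60 patients, moderate
signal (π = 0.5), lateralization task with the bag-of-words representation
and sparse logistic regression:

```
task=side, representation=bw(200), model=logreg_l1, 30 fold records
  accuracy       100.0% +/- 0.0%
  precision_w    100.0% +/- 0.0%
  npv_w          100.0% +/- 0.0%
  specificity_w  100.0% +/- 0.0%
  f1_w           100.0% +/- 0.0%
pooled confusion (summed over folds, averaged over repetitions):
   {'TP': 158.0, 'FP': 0.0, 'FN': 0.0, 'TN': 143.0}
```

At π = 0.5 the planted class markers make the task separable, so the
protocol recovers the signal perfectly; with π = 0 (no signal) the same
pipeline returns chance-level weighted F1 ≈ 0.5, and the response is
monotone in between — that calibration curve is what the acceptance suite
checks. The other examples cover corpus generation and filtering (`01`),
preprocessing (`02`), the bag-of-words inventory (`03`), embedding training
and intrinsic evaluation (`04`), and patient-level holdout generalization
(`06`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the pipeline end-to-end on a freshly generated synthetic corpus:
planting and recovering filter violations, preprocessing, patient-level
splitting, embedding training with intrinsic evaluation, one repeated nested
cross-validation configuration, and the holdout table; it prints each
computed quantity and writes a JSON summary to `--out`.
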