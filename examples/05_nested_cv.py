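"""Classify seizure lateralization with repeated nested cross-validation.

Runs the full protocol on a synthetic corpus: stratified 10-fold outer CV,
10-fold inner hyperparameter search maximizing weighted F1, standardization
and representation fitting local to each training fold, three repetitions
with shuffling seeds 0, 1, 2.  Reports the mean +/- sd of per-trial median
metrics and the pooled confusion counts.
"""

from ezloc import (
    GeneratorSpec,
    NormalizationResources,
    generate_corpus,
    preprocess_corpus,
)
from ezloc.corpus import ExperimentConfig
from ezloc.experiment import run_nested_cv

corpus, _ = generate_corpus(
    GeneratorSpec(n_patients=60, signal_strength=0.5, seed=0)
)
docs = preprocess_corpus(corpus, NormalizationResources.default())

config = ExperimentConfig(task="side", representation="bw",
                          model="logreg_l1", n_features=200,
                          seeds=(0, 1, 2), n_repeats=3)
result = run_nested_cv(docs, "bw", "logreg_l1", config)

print(f"task=side, representation=bw(200), model=logreg_l1, "
      f"{len(result.fold_records)} fold records")
for metric, (mu, sd) in result.aggregate.items():
    print(f"  {metric:14s} {100 * mu:5.1f}% +/- {100 * sd:.1f}%")
print("pooled confusion (summed over folds, averaged over repetitions):")
print("  ", {k: round(v, 1) for k, v in result.pooled_confusion.items()})
# The aggregate is the mean over the three repetitions of the per-repetition
# median across the ten outer folds; 'left' is the positive class.
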