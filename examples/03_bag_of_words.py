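"""Build the mixed character/word n-gram bag-of-words representation.

The feature budget is split 20% character n-grams (n = 2, 3; robust to
misspellings) and 80% word n-grams (n = 1..4; short-range context), ranked by
corpus frequency on the learning set only.
"""

from ezloc import (
    GeneratorSpec,
    NormalizationResources,
    generate_corpus,
    preprocess_corpus,
)
from ezloc.bow import fit_vocabulary, transform

corpus, _ = generate_corpus(GeneratorSpec(n_patients=40, seed=0))
docs = preprocess_corpus(corpus, NormalizationResources.default())

inventory = fit_vocabulary(docs, total_features=200)
print(f"inventory: {len(inventory.char_ngrams)} char + "
      f"{len(inventory.word_ngrams)} word n-grams "
      f"(budgets {inventory.char_budget}/{inventory.word_budget})")
print("top char n-grams:", list(inventory.char_ngrams[:8]))
print("top word n-grams:", [" ".join(g) for g in inventory.word_ngrams[:8]])

fm = transform(docs[:3], inventory)
print(f"feature matrix: {fm.values.shape[0]} documents x "
      f"{fm.values.shape[1]} features")
row = fm.values[0]
nz = row.nonzero()[0]
print("document 0 counts:",
      {fm.feature_names[j]: int(row[j]) for j in nz[:6]})
# Counts are raw term frequencies; standardization is a fold-local step of
# the cross-validation runner.
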