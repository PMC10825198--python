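"""Train the word embedding and inspect it with the intrinsic evaluators.

The skip-gram model trains on seizure descriptions plus longer EMR excerpts
(more text, complete sentences).  Before pooling document vectors, the word
space is checked directly: nearest neighbours by cosine similarity, word
analogies solved with 3CosAdd, and outlier detection in small word groups.
"""

from ezloc import (
    GeneratorSpec,
    NormalizationResources,
    generate_analogy_corpus,
    generate_corpus,
    generate_emr_corpus,
    pool_mean,
    preprocess_corpus,
    train_embedding,
)
from ezloc.corpus import EmbeddingParams
from ezloc.embedding_eval import detect_outlier, most_similar, solve_analogy
from ezloc.synthetic import ANALOGY_QUERY

resources = NormalizationResources.default()
spec = GeneratorSpec(n_patients=60, signal_strength=0.6, seed=0)
corpus, _ = generate_corpus(spec)
docs = preprocess_corpus(corpus, resources)
emr = preprocess_corpus(generate_emr_corpus(spec, 30), resources)

model = train_embedding(docs + emr, EmbeddingParams(epochs=50, seed=0))
print(f"vocabulary {len(model.vocabulary)} words, dimension {model.dimension}")

for target in ("crisi", "temporalide"):
    neighbours = ", ".join(w for w, _ in most_similar(model, target, k=5))
    print(f"most similar to {target}: {neighbours}")

group = ["braccio", "gamba", "mano", "crisi"]
print(f"outlier in {group}: {detect_outlier(model, group)}")

doc = docs[0]
print(f"mean-pooled document vector: shape {pool_mean(doc, model).shape}")

# analogy geometry planted through shared contexts, then actually learned
ana_docs = preprocess_corpus(generate_analogy_corpus(seed=0), resources)
ana_model = train_embedding(
    ana_docs, EmbeddingParams(dimension=32, epochs=150, window=2,
                              negative_samples=5, seed=0)
)
a, a_star, b, b_star = ANALOGY_QUERY
answer = solve_analogy(ana_model, a, a_star, b)
print(f"analogy {a} : {a_star} = {b} : {answer} (expected {b_star})")
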