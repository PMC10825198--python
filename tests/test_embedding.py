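import math

import numpy as np
import pytest

from ezloc import compute_idf, pool_mean, pool_tfidf, train_embedding
from ezloc.corpus import EmbeddingParams
from ezloc.embedding import EmbeddingModel, IdfTable
from ezloc.embedding_eval import cosine_similarity
from tests.conftest import make_doc, make_model


def _sentences(rows, prefix="s"):
    return [make_doc(toks, doc_id=f"{prefix}{i}") for i, toks in enumerate(rows)]


SMALL_PARAMS = dict(dimension=16, epochs=40, negative_samples=5, seed=0)


class TestTraining:
    def test_min_count_excludes_rare_words(self):
        docs = _sentences([["mano", "gamba", "gamba"], ["gamba", "piede",
                                                        "piede"]])
        model = train_embedding(docs, EmbeddingParams(**SMALL_PARAMS))
        assert "mano" not in model
        assert "gamba" in model

    def test_default_dimension_is_100(self):
        docs = _sentences([["a", "b"] * 4, ["b", "c"] * 4])
        model = train_embedding(docs, EmbeddingParams(epochs=2, seed=0))
        assert model.vectors.shape[1] == 100

    def test_empty_vocabulary_is_an_error(self):
        docs = _sentences([["unico"]])
        with pytest.raises(ValueError, match="min_count"):
            train_embedding(docs, EmbeddingParams(epochs=1, seed=0))

    def test_deterministic_given_seed(self):
        docs = _sentences([["a", "b", "c", "d"] * 3, ["c", "d", "e", "f"] * 3])
        p = EmbeddingParams(**SMALL_PARAMS)
        m1, m2 = train_embedding(docs, p), train_embedding(docs, p)
        assert m1.vocabulary == m2.vocabulary
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_planted_cooccurrence_beats_random_pairs(self):
        # two words used in identical contexts end up closer than the 95th
        # percentile of all other vocabulary pairs
        rng = np.random.default_rng(0)
        contexts = [f"ctx{i}" for i in range(6)]
        fillers = [f"bg{i}" for i in range(20)]
        rows = []
        for _ in range(400):
            ctx = [contexts[i] for i in rng.integers(0, 6, size=2)]
            target = "alpha" if rng.random() < 0.5 else "beta"
            noise = [fillers[i] for i in rng.integers(0, 20, size=3)]
            rows.append(noise[:1] + [ctx[0], target, ctx[1]] + noise[1:])
        docs = _sentences(rows)
        model = train_embedding(
            docs, EmbeddingParams(dimension=16, epochs=300,
                                  negative_samples=5, window=2, seed=1)
        )
        planted = cosine_similarity(model.vector("alpha"), model.vector("beta"))
        others = []
        vocab = [w for w in model.vocabulary if w not in ("alpha", "beta")]
        for i, w1 in enumerate(vocab):
            for w2 in vocab[i + 1:]:
                others.append(
                    cosine_similarity(model.vector(w1), model.vector(w2))
                )
        assert planted > np.quantile(others, 0.95)

    def test_cbow_variant_trains(self):
        docs = _sentences([["a", "b", "c", "d"] * 3, ["c", "d", "e", "f"] * 3])
        model = train_embedding(
            docs, EmbeddingParams(dimension=8, epochs=5, seed=0,
                                  algorithm="cbow")
        )
        assert np.all(np.isfinite(model.vectors))


class TestWord2vecFormat:
    def test_roundtrip_bit_exact(self, tmp_path):
        docs = _sentences([["a", "b", "c"] * 3])
        model = train_embedding(docs, EmbeddingParams(dimension=8, epochs=3,
                                                      seed=0))
        path = tmp_path / "vectors.txt"
        model.save_word2vec(path)
        again = EmbeddingModel.load_word2vec(path)
        assert again.vocabulary == model.vocabulary
        assert np.array_equal(again.vectors, model.vectors)
        header = path.read_text().splitlines()[0]
        assert header == f"{len(model.vocabulary)} 8"


class TestIdf:
    def test_smoothed_formula(self):
        docs = _sentences([["a"], ["a", "b"], ["c"], ["c"]])
        idf = compute_idf(docs)
        assert idf.idf("b") == pytest.approx(math.log(2.5) + 1, abs=1e-12)
        assert idf.n_docs_fit == 4

    def test_ubiquitous_term_has_idf_one(self):
        docs = _sentences([["a", "x"], ["a"], ["a", "y"]])
        assert compute_idf(docs).idf("a") == pytest.approx(1.0)

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            compute_idf([])

    def test_matches_sklearn_smooth_idf(self):
        from sklearn.feature_extraction.text import TfidfVectorizer

        rows = [["gamba", "piede"], ["gamba"], ["piede", "mano"], ["mano"]]
        idf = compute_idf(_sentences(rows))
        vec = TfidfVectorizer(analyzer=lambda d: d).fit(rows)
        for term, j in vec.vocabulary_.items():
            assert idf.idf(term) == pytest.approx(vec.idf_[j], abs=1e-12)


class TestPooling:
    def test_mean_examples(self):
        model = make_model({"a": [1, 0], "b": [0, 1]})
        assert pool_mean(make_doc(["a", "b"]), model) == pytest.approx(
            [0.5, 0.5]
        )
        assert pool_mean(make_doc(["a"]), model) == pytest.approx([1, 0])
        assert pool_mean(make_doc(["zz"]), model) == pytest.approx([0, 0])

    def test_tfidf_weighted_average(self):
        model = make_model({"a": [1, 0], "b": [0, 1]})
        idf = IdfTable({"a": 3.0, "b": 1.0}, n_docs_fit=4)
        # single distinct term: idf cancels
        assert pool_tfidf(make_doc(["a", "a"]), model, idf) == pytest.approx(
            [1, 0]
        )
        # weights 3 and 1 -> (0.75, 0.25)
        out = pool_tfidf(make_doc(["a", "b"]), model, idf)
        assert out == pytest.approx([0.75, 0.25])

    def test_uniform_idf_reduces_to_mean(self):
        model = make_model({"a": [1, 2], "b": [3, 0], "c": [-1, 4]})
        idf = IdfTable({"a": 2.0, "b": 2.0, "c": 2.0}, n_docs_fit=3)
        doc = make_doc(["a", "b", "c"])
        assert pool_tfidf(doc, model, idf) == pytest.approx(
            pool_mean(doc, model), abs=1e-12
        )

    def test_convex_hull_bound(self):
        rng = np.random.default_rng(3)
        words = {f"w{i}": list(rng.normal(size=4)) for i in range(6)}
        model = make_model(words)
        idf = IdfTable({w: float(rng.uniform(1, 3)) for w in words}, 6)
        doc = make_doc(["w0", "w2", "w2", "w5"])
        used = np.array([words["w0"], words["w2"], words["w5"]])
        for pooled in (pool_mean(doc, model), pool_tfidf(doc, model, idf)):
            assert np.all(pooled >= used.min(axis=0) - 1e-12)
            assert np.all(pooled <= used.max(axis=0) + 1e-12)

    def test_idf_table_ignores_heldout_documents(self):
        train = _sentences([["a", "b"], ["a"]])
        idf = compute_idf(train)
        digest = idf.digest()
        # transforming unseen documents must not touch the table
        model = make_model({"a": [1, 0], "b": [0, 1]})
        pool_tfidf(make_doc(["b", "zz"]), model, idf)
        assert idf.digest() == digest
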