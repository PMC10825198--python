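import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ezloc.embedding import VocabularyError
from ezloc.embedding_eval import (
    cosine_similarity,
    detect_outlier,
    evaluation_report,
    most_similar,
    solve_analogy,
)
from tests.conftest import make_model


def plain_cosine(u, v):
    """Independent scalar implementation used as the oracle."""
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dot / (nu * nv)


class TestCosine:
    def test_identity_orthogonal_antipodal(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [-1, 0]) == pytest.approx(-1.0)

    def test_zero_vector_is_an_error(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.floats(0.01, 10),
    )
    def test_symmetric_and_scale_invariant(self, u, v, alpha):
        if not any(u) or not any(v):
            return
        assert cosine_similarity(u, v) == pytest.approx(
            cosine_similarity(v, u), abs=1e-12
        )
        assert cosine_similarity([alpha * x for x in u], v) == pytest.approx(
            cosine_similarity(u, v), abs=1e-9
        )


class TestMostSimilar:
    def test_planted_neighbour(self):
        model = make_model({"t": [1, 0], "u": [0.9, 0.1], "v": [0, 1]})
        assert most_similar(model, "t", k=1)[0][0] == "u"

    def test_k_larger_than_vocab_returns_all_others(self):
        model = make_model({"t": [1, 0], "u": [0.9, 0.1], "v": [0, 1]})
        assert [w for w, _ in most_similar(model, "t", k=10)] == ["u", "v"]

    def test_descending_order_and_target_excluded(self):
        rng = np.random.default_rng(0)
        model = make_model({f"w{i}": list(rng.normal(size=4))
                            for i in range(8)})
        ranked = most_similar(model, "w0", k=7)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        assert "w0" not in [w for w, _ in ranked]

    def test_unknown_target(self):
        model = make_model({"t": [1, 0], "u": [0, 1], "v": [1, 1]})
        with pytest.raises(VocabularyError):
            most_similar(model, "zz")


class TestAnalogy:
    def test_planted_offset_geometry(self):
        model = make_model({
            "a": [1, 0], "astar": [1, 1], "b": [3, 0], "bstar": [3, 1],
            "distractor": [-5, -5],
        })
        assert solve_analogy(model, "a", "astar", "b") == "bstar"

    def test_degenerate_equal_pair_returns_nearest_to_b(self):
        model = make_model({
            "a": [1, 0], "b": [0, 1], "near_b": [0.1, 2.0], "far": [1, -1],
        })
        assert solve_analogy(model, "a", "a", "b") == "near_b"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            size = int(rng.integers(5, 15))
            vocab = {f"w{i}": list(rng.normal(size=4)) for i in range(size)}
            model = make_model(vocab)
            a, astar, b = rng.choice(list(vocab), size=3, replace=False)
            query = (np.array(vocab[astar]) - np.array(vocab[a])
                     + np.array(vocab[b]))
            best = min(
                (w for w in vocab if w not in {a, astar, b}),
                key=lambda w: (-plain_cosine(vocab[w], query), w),
            )
            assert solve_analogy(model, a, astar, b) == best


class TestOutlier:
    def test_hand_computed_group(self):
        model = make_model({
            "w": [1, 0], "x": [0.95, 0.05], "y": [0.9, 0.1], "z": [-1, 0],
        })
        assert detect_outlier(model, ["w", "x", "y", "z"]) == "z"

    def test_orthogonal_member(self):
        model = make_model({"a": [1, 0], "b": [1, 0], "c": [1, 0], "d": [0, 1]})
        assert detect_outlier(model, ["a", "b", "c", "d"]) == "d"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        vocab = {f"w{i}": list(rng.normal(size=3)) for i in range(5)}
        model = make_model(vocab)
        words = list(vocab)
        results = {
            detect_outlier(model, list(perm))
            for perm in itertools.permutations(words)
        }
        assert len(results) == 1

    def test_needs_three_distinct_words(self):
        model = make_model({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError):
            detect_outlier(model, ["a", "b"])


class TestPlantedGeometry:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analogy_recovered_from_trained_embedding(self, seed):
        """Shared-context construction induces additive offsets that 3CosAdd
        recovers after actual skip-gram training (not hand-set vectors)."""
        from ezloc import generate_analogy_corpus, preprocess_corpus, train_embedding
        from ezloc.corpus import EmbeddingParams
        from ezloc.preprocess import NormalizationResources

        corpus = generate_analogy_corpus(seed=seed, n_sentences=600)
        docs = preprocess_corpus(corpus, NormalizationResources.default())
        model = train_embedding(
            docs,
            EmbeddingParams(dimension=32, epochs=150, negative_samples=5,
                            window=2, seed=seed),
        )
        from ezloc.synthetic import ANALOGY_QUERY

        a, a_star, b, b_star = ANALOGY_QUERY
        assert solve_analogy(model, a, a_star, b) == b_star


class TestReport:
    def test_sections_and_files(self, tmp_path):
        model = make_model({
            "a": [1, 0], "astar": [1, 1], "b": [3, 0], "bstar": [3, 1],
            "odd": [-4, 2],
        })
        report = evaluation_report(
            model,
            similarity_targets=["a"],
            analogy_queries=[("a", "astar", "b")],
            outlier_groups=[["a", "astar", "odd"]],
            k=3,
            out_dir=tmp_path,
        )
        assert len(report["similarity"][0]["most_similar"]) == 3
        assert report["analogy"][0]["b_star"] == "bstar"
        assert (tmp_path / "similarity.csv").exists()
        assert (tmp_path / "outliers.csv").exists()
        assert (tmp_path / "embedding_eval.json").exists()
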