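"""Intrinsic evaluation of a trained word embedding.

Before the embedding is used to build document representations, its word
space is checked directly:

* *word similarity* — cosine between two word vectors, and the top-k most
  similar words to a target;
* *word analogy* — solve ``a : a* = b : ?`` with 3CosAdd, i.e. the word
  (excluding the three query words) whose vector is most cosine-similar to
  ``v(a*) - v(a) + v(b)``;
* *outlier detection* — in a group of words, the one with the lowest mean
  cosine similarity to the others.

All ties are broken lexicographically so reports are reproducible.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingModel, VocabularyError


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """cos(v1, v2) = v1·v2 / (||v1|| ||v2||), clamped to [-1, 1]."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError("vectors have different dimensions")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))


def _all_cosines(model: EmbeddingModel, query: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(model.vectors, axis=1)
    qn = np.linalg.norm(query)
    if qn == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm query")
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = model.vectors @ query / (norms * qn)
    sims = np.where(norms == 0.0, -np.inf, sims)
    return np.clip(sims, -1.0, 1.0)


def _ranked(model: EmbeddingModel, sims: np.ndarray, exclude: set[str]):
    order = sorted(
        (i for i, w in enumerate(model.vocabulary) if w not in exclude),
        key=lambda i: (-sims[i], model.vocabulary[i]),
    )
    return [(model.vocabulary[i], float(sims[i])) for i in order]


def most_similar(
    model: EmbeddingModel, target: str, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k vocabulary words by cosine to ``target`` (target excluded)."""
    if target not in model:
        raise VocabularyError(f"word {target!r} not in vocabulary")
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = _all_cosines(model, model.vector(target))
    return _ranked(model, sims, {target})[:k]


def solve_analogy(model: EmbeddingModel, a: str, a_star: str, b: str) -> str:
    """3CosAdd: argmax over V \\ {a, a*, b} of cos(v_x, v_a* - v_a + v_b)."""
    for w in (a, a_star, b):
        if w not in model:
            raise VocabularyError(f"word {w!r} not in vocabulary")
    query = model.vector(a_star) - model.vector(a) + model.vector(b)
    ranked = _ranked(model, _all_cosines(model, query), {a, a_star, b})
    if not ranked:
        raise ValueError("vocabulary has no candidate besides the query words")
    return ranked[0][0]


def detect_outlier(model: EmbeddingModel, words: Sequence[str]) -> str:
    """Word with the lowest mean cosine similarity to the rest of the group."""
    words = list(words)
    if len(set(words)) < 3:
        raise ValueError("outlier detection needs >= 3 distinct words")
    for w in words:
        if w not in model:
            raise VocabularyError(f"word {w!r} not in vocabulary")
    means: list[tuple[float, str]] = []
    for w in words:
        sims = [
            cosine_similarity(model.vector(w), model.vector(o))
            for o in words
            if o != w
        ]
        means.append((float(np.mean(sims)), w))
    # lowest mean similarity; ties lexicographic
    means.sort(key=lambda mw: (mw[0], mw[1]))
    return means[0][1]


def evaluation_report(
    model: EmbeddingModel,
    similarity_targets: Sequence[str] = (),
    analogy_queries: Sequence[tuple[str, str, str]] = (),
    outlier_groups: Sequence[Sequence[str]] = (),
    k: int = 5,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the three intrinsic evaluators and optionally write report files.

    The similarity table lists each target with its k most similar words in
    descending cosine order; the outlier table lists each input group with
    the identified outlier.  Written as JSON plus two CSV tables.
    """
    report = {
        "similarity": [
            {
                "target": t,
                "most_similar": [
                    {"word": w, "score": s} for w, s in most_similar(model, t, k)
                ],
            }
            for t in similarity_targets
        ],
        "analogy": [
            {"a": a, "a_star": a_star, "b": b,
             "b_star": solve_analogy(model, a, a_star, b)}
            for a, a_star, b in analogy_queries
        ],
        "outlier": [
            {"words": list(group), "outlier": detect_outlier(model, group)}
            for group in outlier_groups
        ],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "embedding_eval.json").write_text(
            json.dumps(report, ensure_ascii=False, indent=2), encoding="utf-8"
        )
        with (out_dir / "similarity.csv").open("w", newline="",
                                               encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["target_word", "most_similar_words"])
            for row in report["similarity"]:
                writer.writerow(
                    [row["target"],
                     ", ".join(e["word"] for e in row["most_similar"])]
                )
        with (out_dir / "outliers.csv").open("w", newline="",
                                             encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["input_words", "outlier"])
            for row in report["outlier"]:
                writer.writerow([", ".join(row["words"]), row["outlier"]])
    return report
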