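"""Bag-of-words (*bw*) representation over mixed character/word n-grams.

Character n-grams (n = 2, 3) are extracted within tokens (they never cross a
word boundary) and make the representation robust to misspellings; word
n-grams (n = 1..4) retain short-range context.  The feature budget is split
20% / 80% between the two groups, and within each group only the most
frequent n-grams on the learning set are retained (ties broken
lexicographically, for determinism).  Counts are raw term frequencies;
feature scaling is a later, fold-local step of the experiment runner.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import TokenDocument

logger = logging.getLogger("ezloc")

CHAR_NGRAM_SIZES = (2, 3)
WORD_NGRAM_SIZES = (1, 2, 3, 4)
CHAR_FRACTION = 0.2


def char_ngrams(tokens: Sequence[str]) -> Iterable[str]:
    """All character n-grams (n in {2,3}) within each token."""
    for tok in tokens:
        for n in CHAR_NGRAM_SIZES:
            for i in range(len(tok) - n + 1):
                yield tok[i : i + n]


def word_ngrams(tokens: Sequence[str]) -> Iterable[tuple[str, ...]]:
    """All word n-grams (n in 1..4) of the token sequence."""
    for n in WORD_NGRAM_SIZES:
        for i in range(len(tokens) - n + 1):
            yield tuple(tokens[i : i + n])


def split_budget(total_features: int) -> tuple[int, int]:
    """20/80 char/word split; round half away from zero on the char side."""
    char_budget = int(math.floor(CHAR_FRACTION * total_features + 0.5))
    return char_budget, total_features - char_budget


@dataclass(frozen=True)
class NgramInventory:
    """Fitted *bw* feature space: ordered char block then word block."""

    char_ngrams: tuple[str, ...]
    word_ngrams: tuple[tuple[str, ...], ...]
    total_features: int
    char_budget: int
    word_budget: int
    fit_doc_count: int

    @property
    def feature_names(self) -> list[str]:
        return [f"char:{g}" for g in self.char_ngrams] + [
            "word:" + " ".join(g) for g in self.word_ngrams
        ]

    def __len__(self) -> int:
        return len(self.char_ngrams) + len(self.word_ngrams)

    def digest(self) -> str:
        """Stable hash of the fitted feature space (leakage guard)."""
        blob = json.dumps(
            {
                "char": list(self.char_ngrams),
                "word": [list(g) for g in self.word_ngrams],
                "budgets": [self.char_budget, self.word_budget],
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "char_ngrams": list(self.char_ngrams),
            "word_ngrams": [list(g) for g in self.word_ngrams],
            "total_features": self.total_features,
            "char_budget": self.char_budget,
            "word_budget": self.word_budget,
            "fit_doc_count": self.fit_doc_count,
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=2), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NgramInventory":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            char_ngrams=tuple(payload["char_ngrams"]),
            word_ngrams=tuple(tuple(g) for g in payload["word_ngrams"]),
            total_features=payload["total_features"],
            char_budget=payload["char_budget"],
            word_budget=payload["word_budget"],
            fit_doc_count=payload["fit_doc_count"],
        )


def _top_k(counts: Counter, k: int) -> list:
    # rank by descending corpus count, ties lexicographically ascending
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [item for item, _ in ranked[:k]]


def doc_ngram_counters(
    doc: TokenDocument, cache: dict | None = None
) -> tuple[Counter, Counter]:
    """Per-document (char, word) n-gram counts, optionally memoized by doc_id.

    The counters are a pure function of one document, so sharing a cache
    across cross-validation folds cannot leak information between them —
    fold-level fits only ever sum the counters of their own training docs.
    """
    if cache is not None and doc.doc_id in cache:
        return cache[doc.doc_id]
    counters = (Counter(char_ngrams(doc.tokens)), Counter(word_ngrams(doc.tokens)))
    if cache is not None:
        cache[doc.doc_id] = counters
    return counters


def fit_vocabulary(
    train_docs: Sequence[TokenDocument],
    total_features: int,
    counter_cache: dict | None = None,
) -> NgramInventory:
    """Fit the n-gram inventory on learning-set documents only."""
    if total_features < 5:
        raise ValueError("total_features must be >= 5")
    char_budget, word_budget = split_budget(total_features)
    char_counts: Counter = Counter()
    word_counts: Counter = Counter()
    for doc in train_docs:
        cc, wc = doc_ngram_counters(doc, counter_cache)
        char_counts.update(cc)
        word_counts.update(wc)
    chars = _top_k(char_counts, char_budget)
    words = _top_k(word_counts, word_budget)
    if len(chars) < char_budget or len(words) < word_budget:
        logger.warning(
            "n-gram shortfall: %d/%d char, %d/%d word features available",
            len(chars), char_budget, len(words), word_budget,
        )
    return NgramInventory(
        char_ngrams=tuple(chars),
        word_ngrams=tuple(words),
        total_features=total_features,
        char_budget=char_budget,
        word_budget=word_budget,
        fit_doc_count=len(train_docs),
    )


@dataclass
class FeatureMatrix:
    doc_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # n_documents x n_features

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.doc_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape inconsistent with labels")


def transform(
    docs: Sequence[TokenDocument],
    inventory: NgramInventory,
    counter_cache: dict | None = None,
) -> FeatureMatrix:
    """Count occurrences of each inventory feature per document.

    Out-of-inventory patterns are ignored; empty documents yield zero rows.
    """
    char_index = {g: j for j, g in enumerate(inventory.char_ngrams)}
    offset = len(inventory.char_ngrams)
    word_index = {g: offset + j for j, g in enumerate(inventory.word_ngrams)}
    values = np.zeros((len(docs), len(inventory)), dtype=np.int64)
    for i, doc in enumerate(docs):
        row = values[i]
        cc, wc = doc_ngram_counters(doc, counter_cache)
        for g, count in cc.items():
            j = char_index.get(g)
            if j is not None:
                row[j] = count
        for g, count in wc.items():
            j = word_index.get(g)
            if j is not None:
                row[j] = count
    return FeatureMatrix(
        doc_ids=[d.doc_id for d in docs],
        feature_names=inventory.feature_names,
        values=values,
    )
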