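"""Word embeddings and the *mean* / *tfidf* document representations.

Words are mapped to dense vectors in R^D (default D = 100) with a word2vec
model trained on the learning-set seizure descriptions together with the
unlabeled EMR excerpts (more text, syntactically complete sentences).  The
trainer is an in-house, fully vectorized implementation of skip-gram with
negative sampling (CBOW available as an option): the clinical-Italian domain
has no usable pretrained vectors, and the corpus is small enough that a
numpy SGD loop trains in seconds to minutes.

Document vectors are built from word vectors in two ways:

* ``pool_mean`` — the unweighted average of the vectors of all in-vocabulary
  tokens (with multiplicity);
* ``pool_tfidf`` — the average weighted by tf·idf, with the smoothed idf
  ``ln((1 + N) / (1 + df)) + 1`` fitted on learning-set documents only.

Out-of-vocabulary tokens are skipped; a document with no in-vocabulary token
maps to the zero vector (logged), so held-out transforms never fail.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import EmbeddingParams, TokenDocument

logger = logging.getLogger("ezloc")

_INITIAL_LR = 0.025
_FINAL_LR = 1e-4
_NOISE_EXPONENT = 0.75
_BATCH = 1024


class VocabularyError(KeyError):
    """A query word is not in the embedding vocabulary."""


@dataclass
class EmbeddingModel:
    """Trained word embedding: vocabulary V -> vectors in R^D."""

    vocabulary: tuple[str, ...]
    vectors: np.ndarray  # |V| x D
    params: EmbeddingParams
    training_corpus_digest: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("vector count does not match vocabulary size")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self._index[word]]
        except KeyError:
            raise VocabularyError(f"word {word!r} not in vocabulary") from None

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update("\x00".join(self.vocabulary).encode())
        h.update(np.ascontiguousarray(self.vectors).tobytes())
        return h.hexdigest()

    # --- word2vec text format ------------------------------------------
    def save_word2vec(self, path: str | Path) -> None:
        """Standard text format: header ``|V| D``, then word + D floats."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dimension}\n")
            for word, row in zip(self.vocabulary, self.vectors):
                fh.write(word + " " + " ".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def load_word2vec(
        cls, path: str | Path, params: EmbeddingParams | None = None
    ) -> "EmbeddingModel":
        with Path(path).open(encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words: list[str] = []
            rows = np.empty((n, dim), dtype=np.float64)
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                words.append(parts[0])
                rows[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(
            vocabulary=tuple(words),
            vectors=rows,
            params=params or EmbeddingParams(dimension=dim),
        )


def _corpus_digest(docs: Sequence[TokenDocument]) -> str:
    h = hashlib.sha256()
    for doc in docs:
        h.update("\x1f".join(doc.tokens).encode())
        h.update(b"\x1e")
    return h.hexdigest()


def _build_vocab(
    docs: Sequence[TokenDocument], min_count: int
) -> tuple[list[str], np.ndarray]:
    counts: Counter = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    kept = [(w, c) for w, c in counts.items() if c >= min_count]
    # descending count, ties lexicographic: deterministic vocabulary order
    kept.sort(key=lambda wc: (-wc[1], wc[0]))
    words = [w for w, _ in kept]
    freqs = np.array([c for _, c in kept], dtype=np.float64)
    return words, freqs


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _skipgram_pairs(
    sentences: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for ids in sentences:
        n = len(ids)
        if n < 2:
            continue
        # dynamic window size per center position, as in word2vec
        spans = rng.integers(1, window + 1, size=n)
        for i in range(n):
            lo = max(0, i - spans[i])
            hi = min(n, i + spans[i] + 1)
            ctx = np.concatenate([ids[lo:i], ids[i + 1 : hi]])
            if len(ctx):
                centers.append(np.full(len(ctx), ids[i]))
                contexts.append(ctx)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return (
        np.concatenate(centers).astype(np.int64),
        np.concatenate(contexts).astype(np.int64),
    )


def train_embedding(
    docs: Sequence[TokenDocument], params: EmbeddingParams | None = None
) -> EmbeddingModel:
    """Train word vectors on tokenized documents (learning set only).

    Deterministic for a fixed corpus, params and seed (single-threaded SGD,
    fixed batch traversal order).
    """
    params = params or EmbeddingParams()
    docs = list(docs)
    if not docs:
        raise ValueError("empty training corpus")
    words, freqs = _build_vocab(docs, params.min_count)
    if not words:
        raise ValueError(
            f"no word reaches min_count={params.min_count}: empty vocabulary"
        )
    index = {w: i for i, w in enumerate(words)}
    sentences = [
        np.array([index[t] for t in doc.tokens if t in index], dtype=np.int64)
        for doc in docs
    ]

    rng = np.random.default_rng(params.seed)
    n_vocab, dim = len(words), params.dimension
    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_vocab, dim))
    w_out = np.zeros((n_vocab, dim))

    noise = freqs ** _NOISE_EXPONENT
    noise_cdf = np.cumsum(noise / noise.sum())

    centers, contexts = _skipgram_pairs(sentences, params.window, rng)
    n_pairs = len(centers)
    if n_pairs == 0:
        logger.warning("no co-occurrence pairs; returning random init vectors")
        return EmbeddingModel(
            tuple(words), w_in, params, training_corpus_digest=_corpus_digest(docs)
        )
    if params.algorithm == "cbow":
        # one example per center position: the averaged window predicts it
        examples = _cbow_examples(sentences, params.window, rng)
        n_examples = len(examples[0])
    else:
        examples = None
        n_examples = n_pairs

    k = params.negative_samples
    total_batches = params.epochs * max(1, math.ceil(n_examples / _BATCH))
    batch_no = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_examples)
        for start in range(0, n_examples, _BATCH):
            sel = order[start : start + _BATCH]
            lr = _INITIAL_LR - (_INITIAL_LR - _FINAL_LR) * (batch_no / total_batches)
            batch_no += 1
            # negatives are shared across the mini-batch (GEMM formulation)
            negs = np.searchsorted(noise_cdf, rng.random(k)).astype(np.int64)
            if params.algorithm == "cbow":
                _cbow_step(w_in, w_out, examples, sel, negs, lr)
            else:
                _sgns_step(w_in, w_out, centers[sel], contexts[sel], negs, lr)
    return EmbeddingModel(
        tuple(words), w_in, params, training_corpus_digest=_corpus_digest(docs)
    )


def _scatter_mean_update(w: np.ndarray, idx: np.ndarray,
                         grads: np.ndarray, lr: float) -> None:
    """w[i] -= lr * mean of grads rows scattered to i.

    Averaging (rather than summing) the within-batch gradients of a row keeps
    the step size bounded for frequent words, which would otherwise diverge
    on small vocabularies where one word recurs hundreds of times per batch.
    """
    buf = np.zeros_like(w)
    np.add.at(buf, idx, grads)
    cnt = np.bincount(idx, minlength=w.shape[0])
    nz = cnt > 0
    w[nz] -= lr * buf[nz] / cnt[nz, None]


def _sgns_step(w_in, w_out, c, o, negs, lr) -> None:
    h = w_in[c]  # B x D
    g_pos = _sigmoid(np.einsum("bd,bd->b", h, w_out[o])) - 1.0  # B
    w_neg = w_out[negs]  # K x D (negatives shared across the batch)
    g_neg = _sigmoid(h @ w_neg.T)  # B x K
    grad_h = g_pos[:, None] * w_out[o] + g_neg @ w_neg
    _scatter_mean_update(w_out, o, g_pos[:, None] * h, lr)
    # each shared negative row receives its batch-mean gradient
    _scatter_mean_update(w_out, negs, (g_neg.T @ h) / h.shape[0], lr)
    _scatter_mean_update(w_in, c, grad_h, lr)


def _cbow_examples(
    sentences: list[np.ndarray], window: int, rng: np.random.Generator
):
    """(center ids, padded context matrix, context mask) for CBOW."""
    centers: list[int] = []
    rows: list[np.ndarray] = []
    width = 2 * window
    for ids in sentences:
        n = len(ids)
        if n < 2:
            continue
        spans = rng.integers(1, window + 1, size=n)
        for i in range(n):
            lo = max(0, i - spans[i])
            hi = min(n, i + spans[i] + 1)
            ctx = np.concatenate([ids[lo:i], ids[i + 1 : hi]])
            if not len(ctx):
                continue
            row = np.full(width, -1, dtype=np.int64)
            row[: len(ctx)] = ctx
            centers.append(int(ids[i]))
            rows.append(row)
    return (
        np.array(centers, dtype=np.int64),
        np.vstack(rows) if rows else np.empty((0, width), dtype=np.int64),
    )


def _cbow_step(w_in, w_out, examples, sel, negs, lr) -> None:
    centers, ctx = examples
    c, rows = centers[sel], ctx[sel]
    mask = rows >= 0
    counts = mask.sum(axis=1, keepdims=True)
    safe = np.where(mask, rows, 0)
    h = (w_in[safe] * mask[..., None]).sum(axis=1) / counts  # B x D
    g_pos = _sigmoid(np.einsum("bd,bd->b", h, w_out[c])) - 1.0
    w_neg = w_out[negs]  # K x D, shared across the batch
    g_neg = _sigmoid(h @ w_neg.T)
    grad_h = g_pos[:, None] * w_out[c] + g_neg @ w_neg
    _scatter_mean_update(w_out, c, g_pos[:, None] * h, lr)
    _scatter_mean_update(w_out, negs, (g_neg.T @ h) / h.shape[0], lr)
    grad_ctx = (grad_h / counts)[:, None, :] * mask[..., None]
    in_idx = safe.ravel()[mask.ravel()]
    in_grads = grad_ctx.reshape(-1, h.shape[1])[mask.ravel()]
    _scatter_mean_update(w_in, in_idx, in_grads, lr)


# --- tf-idf -----------------------------------------------------------------

@dataclass(frozen=True)
class IdfTable:
    """Smoothed inverse document frequencies fitted on the learning set."""

    table: Mapping[str, float]
    n_docs_fit: int

    def idf(self, term: str) -> float:
        default = math.log(1.0 + self.n_docs_fit) + 1.0  # unseen term: df = 0
        return self.table.get(term, default)

    def digest(self) -> str:
        h = hashlib.sha256()
        for term in sorted(self.table):
            h.update(f"{term}\x1f{self.table[term]!r}\x1e".encode())
        h.update(str(self.n_docs_fit).encode())
        return h.hexdigest()


def compute_idf(train_docs: Sequence[TokenDocument]) -> IdfTable:
    """idf(t) = ln((1 + N) / (1 + df(t))) + 1 over learning-set documents."""
    docs = list(train_docs)
    n = len(docs)
    if n == 0:
        raise ValueError("cannot fit idf on an empty corpus")
    df: Counter = Counter()
    for doc in docs:
        df.update(set(doc.tokens))
    table = {
        t: math.log((1.0 + n) / (1.0 + d)) + 1.0 for t, d in df.items()
    }
    return IdfTable(table=table, n_docs_fit=n)


# --- document pooling -------------------------------------------------------

def pool_mean(doc: TokenDocument, model: EmbeddingModel) -> np.ndarray:
    """Unweighted mean of in-vocabulary token vectors (with multiplicity)."""
    rows = [model.vector(t) for t in doc.tokens if t in model]
    if not rows:
        logger.warning("document %s has no in-vocabulary token", doc.doc_id)
        return np.zeros(model.dimension)
    return np.mean(rows, axis=0)


def pool_tfidf(
    doc: TokenDocument, model: EmbeddingModel, idf: IdfTable
) -> np.ndarray:
    """tf·idf-weighted average of word vectors over distinct in-vocab terms."""
    tf = Counter(t for t in doc.tokens if t in model)
    if not tf:
        logger.warning("document %s has no in-vocabulary token", doc.doc_id)
        return np.zeros(model.dimension)
    total = 0.0
    acc = np.zeros(model.dimension)
    for term, count in tf.items():
        w = count * idf.idf(term)
        acc += w * model.vector(term)
        total += w
    if total == 0.0:
        logger.warning("document %s has zero tf-idf mass", doc.doc_id)
        return np.zeros(model.dimension)
    return acc / total


def pool_documents(
    docs: Sequence[TokenDocument],
    model: EmbeddingModel,
    idf: IdfTable | None = None,
) -> np.ndarray:
    """Stack pooled document vectors; tf-idf pooling when ``idf`` is given."""
    if idf is None:
        return np.vstack([pool_mean(d, model) for d in docs])
    return np.vstack([pool_tfidf(d, model, idf) for d in docs])
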