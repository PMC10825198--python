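"""Patient-level splitting, nested cross-validation and holdout evaluation.

The corpus is first split **by patient** into a learning set and a holdout
set (no patient's seizures straddle the split).  On the learning set, each
(task, representation, model) configuration is evaluated with a repeated
stratified nested cross-validation: an outer stratified k-fold (default
k = 10) over seizure documents, an inner stratified k-fold hyperparameter
search on each outer-training portion maximizing weighted F1, and N = 3
repetitions with the shuffling random state equal to the repetition index.
All fitted objects — n-gram inventory, idf table, per-feature standardizer —
are fold-local; the word embedding itself is trained once per learning set
(its training corpus includes unlabeled EMR text, never holdout documents).

Per-trial performance is summarized by the median over folds; the headline
number is the mean (± sd) of the per-trial medians.  Confusion counts are
summed across folds and averaged across repetitions.
"""

from __future__ import annotations

import hashlib
import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import bow
from .corpus import (
    Corpus,
    ExperimentConfig,
    RunLog,
    TASK_LABELS,
    TokenDocument,
)
from .embedding import EmbeddingModel, IdfTable, compute_idf, pool_documents
from .metrics import METRICS, compute_weighted_metrics


class LeakageError(RuntimeError):
    """A fitted object changed during a holdout-set operation."""


# --- splitting --------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    learning_patient_ids: frozenset[str]
    holdout_patient_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.learning_patient_ids & self.holdout_patient_ids:
            raise ValueError("learning and holdout patient sets overlap")


def split_by_patient(
    corpus: Corpus,
    holdout_fraction: float,
    seed: int,
    tasks: Sequence[str] = ("side", "localization"),
    max_attempts: int = 50,
) -> SplitSpec:
    """Assign whole patients to learning/holdout sets, deterministically.

    Patients with labeled seizure documents are checked for stratification:
    every class of every listed task present on one side must be present on
    both (resampled up to ``max_attempts`` times, then an error).
    """
    patients = [
        p for p in corpus.patient_ids
        if any(d.patient_id == p and d.doc_kind == "seizure" for d in corpus)
    ]
    if len(patients) < 2:
        raise ValueError("need at least two patients with seizure documents")
    n_holdout = int(math.floor(holdout_fraction * len(patients) + 0.5))

    patient_labels: dict[str, dict[str, str]] = {}
    for doc in corpus.seizure_documents():
        patient_labels.setdefault(doc.patient_id, {}).update(doc.labels)

    def _stratified(holdout: set[str]) -> bool:
        if not holdout or len(holdout) == len(patients):
            return True
        for task in tasks:
            values = {patient_labels.get(p, {}).get(task) for p in patients}
            values.discard(None)
            for value in values:
                on_hold = any(
                    patient_labels.get(p, {}).get(task) == value for p in holdout
                )
                on_learn = any(
                    patient_labels.get(p, {}).get(task) == value
                    for p in patients if p not in holdout
                )
                if not (on_hold and on_learn):
                    return False
        return True

    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        order = list(rng.permutation(len(patients)))
        holdout = {patients[i] for i in order[:n_holdout]}
        if _stratified(holdout):
            return SplitSpec(
                learning_patient_ids=frozenset(p for p in patients
                                               if p not in holdout),
                holdout_patient_ids=frozenset(holdout),
                seed=seed,
            )
    raise ValueError(
        f"could not produce a class-stratified patient split in {max_attempts} "
        "attempts; a labeled class is too rare for the requested fraction"
    )


def select_task_subset(
    docs: Sequence[TokenDocument], task: str
) -> list[TokenDocument]:
    """Seizure documents carrying a label for ``task``.

    For the frontal-vs-posterior task this automatically restricts to
    extra-temporal patients, because only they carry a sublocalization label.
    """
    if task not in TASK_LABELS:
        raise ValueError(f"unknown task {task!r}")
    subset = [
        d for d in docs
        if d.doc_kind == "seizure" and d.label(task) is not None
    ]
    if not subset:
        raise ValueError(f"no documents labeled for task {task!r}")
    return subset


# --- representations --------------------------------------------------------

class Representation:
    """Fit-on-train / transform-anywhere feature builder."""

    name: str = ""

    def fit(self, docs: Sequence[TokenDocument]) -> "Representation":
        raise NotImplementedError

    def transform(self, docs: Sequence[TokenDocument]) -> np.ndarray:
        raise NotImplementedError

    def digest(self) -> str:
        raise NotImplementedError


class BowRepresentation(Representation):
    name = "bw"

    def __init__(self, n_features: int = 200, counter_cache: dict | None = None):
        self.n_features = n_features
        self.inventory: bow.NgramInventory | None = None
        # per-document counters are label-free and doc-local, safe to share
        self._cache = counter_cache

    def fit(self, docs):
        self.inventory = bow.fit_vocabulary(docs, self.n_features, self._cache)
        return self

    def transform(self, docs):
        if self.inventory is None:
            raise RuntimeError("representation not fitted")
        return bow.transform(docs, self.inventory, self._cache).values.astype(
            np.float64
        )

    def digest(self):
        if self.inventory is None:
            return "unfitted"
        return self.inventory.digest()


class MeanEmbeddingRepresentation(Representation):
    name = "mean"

    def __init__(self, model: EmbeddingModel):
        self.model = model

    def fit(self, docs):
        return self  # embedding is trained once per learning set, upstream

    def transform(self, docs):
        return pool_documents(docs, self.model)

    def digest(self):
        return self.model.digest()


class TfidfEmbeddingRepresentation(Representation):
    name = "tfidf"

    def __init__(self, model: EmbeddingModel):
        self.model = model
        self.idf: IdfTable | None = None

    def fit(self, docs):
        self.idf = compute_idf(docs)
        return self

    def transform(self, docs):
        if self.idf is None:
            raise RuntimeError("representation not fitted")
        return pool_documents(docs, self.model, self.idf)

    def digest(self):
        idf_part = self.idf.digest() if self.idf is not None else "unfitted"
        return hashlib.sha256(
            (self.model.digest() + idf_part).encode()
        ).hexdigest()


def make_representation(
    name: str,
    n_features: int = 200,
    embedding_model: EmbeddingModel | None = None,
) -> Representation:
    if name == "bw":
        return BowRepresentation(n_features)
    if name in ("mean", "tfidf") and embedding_model is None:
        raise ValueError(f"representation {name!r} requires an embedding model")
    if name == "mean":
        return MeanEmbeddingRepresentation(embedding_model)
    if name == "tfidf":
        return TfidfEmbeddingRepresentation(embedding_model)
    raise ValueError(f"unknown representation {name!r}")


# --- models -----------------------------------------------------------------

_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logreg_l1": [{"C": c} for c in _C_GRID],
    "svm_linear": [{"C": c} for c in _C_GRID],
    "svm_rbf": [
        {"C": c, "gamma": g}
        for c in _C_GRID
        for g in ("scale", 1e-3, 1e-2, 1e-1, 1.0)
    ],
    "svm_poly3": [{"C": c} for c in _C_GRID],
}


@dataclass
class ModelSpec:
    family: str
    hyper_grid: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.hyper_grid:
            self.hyper_grid = [dict(h) for h in DEFAULT_GRIDS[self.family]]

    def make_estimator(self, hypers: Mapping):
        # tol/max_iter bound the solvers on adversarially noisy folds without
        # changing results on well-posed ones
        if self.family == "logreg_l1":
            return LogisticRegression(
                l1_ratio=1.0, solver="liblinear", max_iter=200, tol=1e-2,
                random_state=0, **hypers,
            )
        if self.family == "svm_linear":
            return SVC(kernel="linear", max_iter=100_000, **hypers)
        if self.family == "svm_rbf":
            return SVC(kernel="rbf", max_iter=100_000, **hypers)
        if self.family == "svm_poly3":
            return SVC(kernel="poly", degree=3, gamma="scale",
                       max_iter=100_000, **hypers)
        raise AssertionError(self.family)


# --- nested CV --------------------------------------------------------------

@dataclass
class FoldRecord:
    seed: int
    fold_index: int
    chosen_hypers: dict
    metrics: dict[str, float]
    confusion: dict[str, int]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.confusion.values())
        if total <= 0:
            raise ValueError("confusion counts empty")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    fold_records: list[FoldRecord]
    per_trial_medians: dict[int, dict[str, float]]
    aggregate: dict[str, tuple[float, float]]
    pooled_confusion: dict[str, float]

    def mean_f1(self) -> float:
        return self.aggregate["f1_w"][0]


def _fit_estimator(estimator, X, y):
    """Fit while silencing unconverged-solver chatter on degenerate folds."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        return estimator.fit(X, y)


def _scaler_digest(scaler: StandardScaler) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(scaler.mean_).tobytes())
    h.update(np.ascontiguousarray(scaler.scale_).tobytes())
    return h.hexdigest()


def _inner_select(
    train_docs: list[TokenDocument],
    y_train: np.ndarray,
    rep_factory: Callable[[], Representation],
    model_spec: ModelSpec,
    k_inner: int,
    seed: int,
    positive: str,
    negative: str,
) -> dict:
    """Inner stratified k-fold grid search maximizing weighted F1."""
    k = min(k_inner, int(np.min(np.unique(y_train, return_counts=True)[1])))
    k = max(2, k)
    inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.zeros(len(model_spec.hyper_grid))
    idx = np.arange(len(train_docs))
    for tr, va in inner.split(idx, y_train):
        rep = rep_factory().fit([train_docs[i] for i in tr])
        X_tr = rep.transform([train_docs[i] for i in tr])
        X_va = rep.transform([train_docs[i] for i in va])
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_va = scaler.transform(X_tr), scaler.transform(X_va)
        for j, hypers in enumerate(model_spec.hyper_grid):
            est = _fit_estimator(
                model_spec.make_estimator(hypers), X_tr, y_train[tr]
            )
            pred = est.predict(X_va)
            m, _, _ = compute_weighted_metrics(
                list(y_train[va]), list(pred), positive, negative
            )
            scores[j] += m["f1_w"]
    best = int(np.argmax(scores))  # first-in-grid tie-break
    return dict(model_spec.hyper_grid[best])


def run_nested_cv(
    dataset: Sequence[TokenDocument],
    representation: str | Callable[[], Representation],
    model_spec: ModelSpec | str,
    config: ExperimentConfig,
    embedding_model: EmbeddingModel | None = None,
    log: RunLog | None = None,
) -> ExperimentResult:
    """Repeated stratified nested cross-validation on the learning set.

    ``dataset`` must be labeled for ``config.task``; ``representation`` may be
    one of {"bw", "mean", "tfidf"} (embedding-based ones need
    ``embedding_model``) or a zero-argument factory of a fresh
    :class:`Representation`.
    """
    docs = select_task_subset(dataset, config.task)
    positive, negative = TASK_LABELS[config.task]
    y = np.array([d.label(config.task) for d in docs])
    if len(set(y)) < 2:
        raise ValueError("dataset must contain both classes")

    if isinstance(model_spec, str):
        model_spec = ModelSpec(model_spec)
    if callable(representation):
        rep_factory = representation
    elif representation == "bw":
        cache: dict = {}  # per-document counters, shared across folds safely

        def rep_factory() -> Representation:
            return BowRepresentation(config.n_features, counter_cache=cache)
    else:
        rep_factory = lambda: make_representation(  # noqa: E731
            representation, config.n_features, embedding_model
        )

    fold_records: list[FoldRecord] = []
    idx = np.arange(len(docs))
    for seed in config.seeds:
        outer = StratifiedKFold(
            n_splits=config.k_outer, shuffle=True, random_state=seed
        )
        for fold_index, (tr, te) in enumerate(outer.split(idx, y)):
            train_docs = [docs[i] for i in tr]
            test_docs = [docs[i] for i in te]
            chosen = _inner_select(
                train_docs, y[tr], rep_factory, model_spec,
                config.k_inner, seed, positive, negative,
            )
            rep = rep_factory().fit(train_docs)
            X_tr = rep.transform(train_docs)
            X_te = rep.transform(test_docs)
            scaler = StandardScaler().fit(X_tr)
            est = _fit_estimator(
                model_spec.make_estimator(chosen), scaler.transform(X_tr), y[tr]
            )
            pred = est.predict(scaler.transform(X_te))
            metrics, confusion, flags = compute_weighted_metrics(
                list(y[te]), list(pred), positive, negative
            )
            fold_records.append(
                FoldRecord(
                    seed=seed,
                    fold_index=fold_index,
                    chosen_hypers=chosen,
                    metrics=metrics,
                    confusion=confusion,
                    flags=tuple(flags),
                )
            )
        if log is not None:
            log.stage(
                "nested_cv",
                f"seed {seed}: outer {config.k_outer}-fold, "
                f"inner {config.k_inner}-fold grid search",
                n_documents=len(docs),
            )
    return summarize(config, fold_records)


def summarize(
    config: ExperimentConfig, fold_records: list[FoldRecord]
) -> ExperimentResult:
    """Aggregate fold records: per-trial medians, their mean/sd, pooled
    confusion (summed across folds, averaged across repetitions)."""
    per_trial: dict[int, dict[str, float]] = {}
    for seed in sorted({r.seed for r in fold_records}):
        recs = [r for r in fold_records if r.seed == seed]
        per_trial[seed] = {
            m: float(statistics.median(r.metrics[m] for r in recs))
            for m in METRICS
        }
    aggregate = {}
    for m in METRICS:
        values = [per_trial[s][m] for s in per_trial]
        mu = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        aggregate[m] = (mu, sd)
    n_trials = len(per_trial)
    pooled = {
        key: sum(r.confusion[key] for r in fold_records) / n_trials
        for key in ("TP", "FP", "FN", "TN")
    }
    return ExperimentResult(
        config=config,
        fold_records=fold_records,
        per_trial_medians=per_trial,
        aggregate=aggregate,
        pooled_confusion=pooled,
    )


# --- holdout ----------------------------------------------------------------

def evaluate_holdout(
    learning_docs: Sequence[TokenDocument],
    holdout_docs: Sequence[TokenDocument],
    task: str,
    combos: Sequence[tuple[str, str, dict]],
    n_features: int = 200,
    embedding_model: EmbeddingModel | None = None,
) -> list[dict]:
    """Refit on the full learning set and evaluate once on held-out patients.

    ``combos`` lists (representation, model_family, hyperparameters) selected
    on the learning set only.  Digests of every fitted object (inventory or
    idf, scaler, embedding) are asserted unchanged by the holdout transform —
    a deliberate leakage canary raises :class:`LeakageError`.
    """
    if not holdout_docs:
        raise ValueError("holdout set is empty")
    learn = select_task_subset(learning_docs, task)
    hold = select_task_subset(holdout_docs, task)
    positive, negative = TASK_LABELS[task]
    y_learn = [d.label(task) for d in learn]
    y_hold = [d.label(task) for d in hold]

    rows: list[dict] = []
    for rep_name, family, hypers in combos:
        rep = make_representation(rep_name, n_features, embedding_model)
        rep.fit(learn)
        X_learn = rep.transform(learn)
        scaler = StandardScaler().fit(X_learn)
        spec = ModelSpec(family)
        est = _fit_estimator(
            spec.make_estimator(hypers), scaler.transform(X_learn),
            np.array(y_learn),
        )
        rep_digest = rep.digest()
        scaler_digest = _scaler_digest(scaler)
        emb_digest = embedding_model.digest() if embedding_model else None

        X_hold = rep.transform(hold)
        if rep.digest() != rep_digest or _scaler_digest(scaler) != scaler_digest:
            raise LeakageError(
                "a fitted object changed during the holdout transform"
            )
        if emb_digest is not None and embedding_model.digest() != emb_digest:
            raise LeakageError("embedding changed during the holdout transform")
        pred = est.predict(scaler.transform(X_hold))

        metrics, confusion, flags = compute_weighted_metrics(
            y_hold, list(pred), positive, negative
        )
        rows.append(
            {
                "representation": rep_name,
                "model": family,
                "hypers": dict(hypers),
                **metrics,
                "confusion": confusion,
                "flags": list(flags),
            }
        )
    return rows
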