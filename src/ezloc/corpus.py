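"""Domain types, corpus I/O, experiment configuration and run logging.

The unit of analysis is a short free-text description of a single seizure,
written by a clinician after reviewing long-term video-EEG; each description
belongs to a patient and carries up to three binary labels about the putative
epileptogenic zone (EZ): hemisphere (left/right), region (temporal vs
extra-temporal) and, within extra-temporal patients, sub-region (frontal vs
posterior).  A second kind of document — longer anamnestic excerpts from
electronic medical records (EMR) — carries no labels and is used only to
enlarge the embedding-training corpus.

Corpora are stored as UTF-8 JSONL, one record per line with keys
``doc_id, patient_id, text, doc_kind, side, localization, sublocalization``
(the last three nullable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("ezloc")

TASKS = ("side", "localization", "sublocalization")

#: closed label vocabulary per task; first entry is the designated POSITIVE
#: class used for the confusion-matrix orientation (left, extra_temporal,
#: posterior), the second the negative one.
TASK_LABELS: dict[str, tuple[str, str]] = {
    "side": ("left", "right"),
    "localization": ("extra_temporal", "temporal"),
    "sublocalization": ("posterior", "frontal"),
}

REPRESENTATIONS = ("bw", "mean", "tfidf")
MODEL_FAMILIES = ("logreg_l1", "svm_linear", "svm_rbf", "svm_poly3")

METRIC_NAMES = ("accuracy", "precision_w", "npv_w", "specificity_w", "f1_w")


class CorpusError(ValueError):
    """Schema or integrity violation in a corpus record."""


@dataclass(frozen=True)
class RawDocument:
    """One seizure description or EMR excerpt, prior to any normalization."""

    doc_id: str
    patient_id: str
    text: str
    doc_kind: str = "seizure"  # {"seizure", "emr"}
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"document {self.doc_id!r}: text is empty")
        if self.doc_kind not in ("seizure", "emr"):
            raise CorpusError(
                f"document {self.doc_id!r}: unknown doc_kind {self.doc_kind!r}"
            )
        if self.doc_kind == "emr" and self.labels:
            raise CorpusError(
                f"document {self.doc_id!r}: EMR documents carry no labels"
            )
        for task, value in self.labels.items():
            if task not in TASK_LABELS:
                raise CorpusError(
                    f"document {self.doc_id!r}: unknown label field {task!r}"
                )
            if value not in TASK_LABELS[task]:
                raise CorpusError(
                    f"document {self.doc_id!r}: unknown value {value!r} for "
                    f"label {task!r} (expected one of {TASK_LABELS[task]})"
                )
        if "sublocalization" in self.labels and (
            self.labels.get("localization") != "extra_temporal"
        ):
            raise CorpusError(
                f"document {self.doc_id!r}: sublocalization requires "
                "localization=extra_temporal"
            )

    def label(self, task: str) -> str | None:
        return self.labels.get(task)


@dataclass(frozen=True)
class TokenDocument:
    """Ordered lemma sequence after the full normalization chain."""

    doc_id: str
    patient_id: str
    tokens: tuple[str, ...]
    doc_kind: str = "seizure"
    labels: Mapping[str, str] = field(default_factory=dict)

    def label(self, task: str) -> str | None:
        return self.labels.get(task)


@dataclass
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: list[RawDocument]
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for doc in self.documents:
            if doc.patient_id not in seen:
                seen.add(doc.patient_id)
                out.append(doc.patient_id)
        return out

    def seizure_documents(self) -> list[RawDocument]:
        return [d for d in self.documents if d.doc_kind == "seizure"]

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        wanted = set(doc_ids)
        return Corpus(
            [d for d in self.documents if d.doc_id in wanted],
            provenance=self.provenance,
            seed=self.seed,
        )


_JSONL_LABEL_KEYS = ("side", "localization", "sublocalization")


def _record_to_document(record: Mapping, lineno: int) -> RawDocument:
    for key in ("doc_id", "patient_id", "text", "doc_kind"):
        if key not in record or record[key] is None:
            raise CorpusError(f"record {lineno}: missing required field {key!r}")
    labels = {
        k: record[k]
        for k in _JSONL_LABEL_KEYS
        if record.get(k) is not None
    }
    return RawDocument(
        doc_id=str(record["doc_id"]),
        patient_id=str(record["patient_id"]),
        text=record["text"],
        doc_kind=record["doc_kind"],
        labels=labels,
    )


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from disk.

    ``jsonl`` expects one JSON object per line; ``delimited`` expects a
    tab-separated table with a header row using the same field names.
    Records with unknown label values raise, they are never dropped.
    """
    path = Path(path)
    docs: list[RawDocument] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                docs.append(_record_to_document(json.loads(line), lineno))
    elif format == "delimited":
        import csv

        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=2):
                rec = {k: (v if v != "" else None) for k, v in row.items()}
                docs.append(_record_to_document(rec, lineno))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return Corpus(docs, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL (inverse of :func:`read_corpus`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            record = {
                "doc_id": doc.doc_id,
                "patient_id": doc.patient_id,
                "text": doc.text,
                "doc_kind": doc.doc_kind,
            }
            for key in _JSONL_LABEL_KEYS:
                record[key] = doc.labels.get(key)
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


@dataclass
class EmbeddingParams:
    """Hyperparameters of the skip-gram/negative-sampling word embedding."""

    dimension: int = 100
    negative_samples: int = 10
    epochs: int = 300
    min_count: int = 2
    window: int = 3
    algorithm: str = "skipgram"  # {"skipgram", "cbow"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        for name in ("negative_samples", "epochs", "min_count", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.algorithm not in ("skipgram", "cbow"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class ExperimentConfig:
    """Full specification of one classification experiment."""

    task: str = "side"
    representation: str = "bw"
    model: str = "logreg_l1"
    n_features: int = 200  # bag-of-words only
    k_outer: int = 10
    k_inner: int = 10
    n_repeats: int = 3
    seeds: tuple[int, ...] = (0, 1, 2)
    embedding_params: EmbeddingParams = field(default_factory=EmbeddingParams)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"unknown model {self.model!r}")
        self.seeds = tuple(self.seeds)
        if len(self.seeds) != self.n_repeats:
            raise ValueError("seeds must have length n_repeats")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        emb = raw.pop("embedding_params", None)
        cfg = cls(**raw)
        if emb:
            cfg.embedding_params = EmbeddingParams(**emb)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunLog:
    """Append-only log of pipeline stages for one run (auditable runs).

    Records the resolved config hash, every seed, a short description of each
    stage, and document in/out counts per filter.
    """

    config_digest: str = ""
    seeds: tuple[int, ...] = ()
    events: list[dict] = field(default_factory=list)

    def stage(self, name: str, description: str, **counts: int) -> None:
        event = {"stage": name, "description": description, **counts}
        self.events.append(event)
        logger.info("stage %s: %s %s", name, description, counts or "")

    def write(self, path: str | Path) -> None:
        payload = {
            "config_digest": self.config_digest,
            "seeds": list(self.seeds),
            "events": self.events,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
        )


# --- result serialization -------------------------------------------------

def write_result(result, out_dir: str | Path) -> dict[str, Path]:
    """Write an :class:`~ezloc.experiment.ExperimentResult` to ``out_dir``.

    Emits ``fold_metrics.csv`` (seed, fold, metric, value — full precision so
    re-reading reproduces the floats bit-exactly), ``aggregate.csv`` (mean and
    sd of per-trial medians per metric), ``confusion.json`` (pooled confusion
    counts) and ``config.json`` (config echo).
    """
    if not result.fold_records:
        raise ValueError("empty result: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    import csv

    paths = {
        "fold_metrics": out_dir / "fold_metrics.csv",
        "aggregate": out_dir / "aggregate.csv",
        "confusion": out_dir / "confusion.json",
        "config": out_dir / "config.json",
    }
    with paths["fold_metrics"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seed", "fold", "metric", "value"])
        for rec in result.fold_records:
            for metric in METRIC_NAMES:
                # repr round-trips Python floats exactly
                writer.writerow(
                    [rec.seed, rec.fold_index, metric, repr(rec.metrics[metric])]
                )
    with paths["aggregate"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "mean", "sd"])
        for metric in METRIC_NAMES:
            mu, sd = result.aggregate[metric]
            writer.writerow([metric, repr(mu), repr(sd)])
    with paths["confusion"].open("w", encoding="utf-8") as fh:
        json.dump(result.pooled_confusion, fh, indent=2)
    with paths["config"].open("w", encoding="utf-8") as fh:
        json.dump(result.config.to_dict(), fh, indent=2)
    return paths


def read_fold_metrics(path: str | Path) -> list[tuple[int, int, str, float]]:
    """Inverse of the per-fold table written by :func:`write_result`."""
    import csv

    rows: list[tuple[int, int, str, float]] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            rows.append(
                (int(row["seed"]), int(row["fold"]), row["metric"],
                 float(row["value"]))
            )
    return rows


def aggregate_trial_medians(per_trial_medians: Sequence[float]) -> tuple[float, float]:
    """Mean and (population=sample, ddof=1) sd of per-trial median metrics."""
    mu = statistics.fmean(per_trial_medians)
    sd = statistics.stdev(per_trial_medians) if len(per_trial_medians) > 1 else 0.0
    return mu, sd
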