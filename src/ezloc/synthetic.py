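"""Synthetic seizure-description and EMR corpora with known ground truth.

Real seizure semiology corpora are private clinical data, so every stage of
the pipeline is exercised on generated corpora that reproduce the statistical
structure the pipeline assumes:

* documents are grouped by patient (seizure counts follow a truncated
  negative binomial moment-matched to mean 4.39, sd 3.63 on support 1..17);
* labels live at the patient level (side; temporal vs extra-temporal; and,
  within extra-temporal patients, frontal vs posterior);
* each class owns a disjoint set of invented marker lemmas; the per-task
  signal strength pi in [0, 1] scales how many markers a document receives
  (pi = 0: no marker ever appears, text is independent of the label);
* clinician style variability: each document is written in one of several
  style profiles that perturb the background lemma weights and typical
  document length;
* raw-text noise at configurable rates: dates/times, bracketed annotations,
  electrode names ("B2"), clinical abbreviations (aass, aoo) and
  character-swap misspellings.

The generated prose is Italian-flavored nonsense: it exercises the
preprocessing resources realistically but carries no clinical meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import Corpus, RawDocument

# --- default lexicon --------------------------------------------------------

#: invented, mutually disjoint marker lemmas per class
DEFAULT_MARKER_VOCAB: dict[str, tuple[str, ...]] = {
    "left": ("sinistrante", "levoverso", "mancinismo", "levoclonia"),
    "right": ("destrante", "dextroverso", "destrismo", "dextroclonia"),
    "temporal": ("temporalide", "ippocampide", "epigastride", "oroalimentare"),
    "extra_temporal": ("extratemporalide", "convessitario", "rolandide",
                       "ipermotorio"),
    "frontal": ("frontalide", "premotoride", "cingolide", "sprintore"),
    "posterior": ("posterioride", "occipitalide", "parietalide", "visivante"),
}

_TASK_CLASSES = {
    "side": ("left", "right"),
    "localization": ("temporal", "extra_temporal"),
    "sublocalization": ("frontal", "posterior"),
}

DEFAULT_BACKGROUND_VOCAB: tuple[str, ...] = (
    "crisi", "paziente", "braccio", "gamba", "mano", "piede", "occhio",
    "aperto", "chiuso", "arto", "superiore", "inferiore", "scossa", "clonia",
    "mioclonia", "movimento", "sollevamento", "versione", "deviazione",
    "sguardo", "fisso", "capo", "destro", "sinistro", "tono", "tonico",
    "ritmico", "automatismo", "masticazione", "vocalizzazione", "contrazione",
    "flessione", "estensione", "rotazione", "tremore", "rigidita", "volto",
    "bocca", "lingua", "spalla", "tronco", "postura", "esordio", "termine",
    "durata", "sequenza", "evoluzione", "contatto", "risposta", "comando",
    "verbale", "motorio", "sensazione", "aura", "paura", "sudorazione",
    "pallore", "rossore", "respiro", "deglutizione", "ammiccamento",
    "grimace", "smorfia", "torsione", "oscillazione", "pedalamento",
    "sfregamento", "manipolazione", "afferramento", "rilascio", "caduta",
    "recupero", "confusione", "orientamento", "memoria", "linguaggio",
    "comprensione", "esecuzione", "ripetizione", "fase", "inizio", "fine",
)

#: closed-class filler making sentences look like prose (removed by the
#: stop-word filter downstream)
FUNCTION_WORDS: tuple[str, ...] = (
    "il", "la", "di", "e", "con", "per", "in", "su", "che", "non", "si",
    "al", "della", "poi", "dopo",
)

_DATE_TOKENS = ("14:30", "09:15", "12/03/2017", "03/11/2019", "22:05")
_BRACKET_SNIPPETS = ("(elettrodo B2)", "[nota interna]", "(video 3)",
                     "{revisione 2}")
_ELECTRODE_TOKENS = ("B2", "TP4", "F7", "O1", "C3")
_ABBREVIATIONS = ("aass", "aoo")

#: patient-level class prevalences (fractions observed in a surgical
#: drug-resistant cohort: 60/122 left, 59/122 temporal, 29/49 frontal)
_P_LEFT = 60 / 122
_P_TEMPORAL = 59 / 122
_P_FRONTAL = 29 / 49


@dataclass(frozen=True)
class SeizureCountSpec:
    mean: float = 4.39
    sd: float = 3.63
    low: int = 1
    high: int = 17


@dataclass(frozen=True)
class DocLengthSpec:
    mean: float = 36.0
    minimum: int = 22  # keeps every regular document above the 20-token filter


@dataclass
class GeneratorSpec:
    n_patients: int = 122
    seizure_counts: SeizureCountSpec = field(default_factory=SeizureCountSpec)
    signal_strength: float | Mapping[str, float] = 0.6
    marker_vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_VOCAB)
    )
    background_vocab: tuple[str, ...] = DEFAULT_BACKGROUND_VOCAB
    noise_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "date_rate": 0.4,
            "bracket_rate": 0.3,
            "electrode_rate": 0.25,
            "abbreviation_rate": 0.5,
            "misspelling_rate": 0.02,
        }
    )
    clinician_styles: int = 8
    doc_length: DocLengthSpec = field(default_factory=DocLengthSpec)
    short_doc_fraction: float = 0.0
    marker_slots: int = 8  # markers per task ~ Binomial(marker_slots, pi)
    seed: int = 0

    def pi(self, task: str) -> float:
        if isinstance(self.signal_strength, Mapping):
            return float(self.signal_strength.get(task, 0.0))
        return float(self.signal_strength)

    def __post_init__(self) -> None:
        for a, b in _TASK_CLASSES.values():
            if set(self.marker_vocab.get(a, ())) & set(self.marker_vocab.get(b, ())):
                raise ValueError(f"marker sets for {a}/{b} are not disjoint")
        for task in _TASK_CLASSES:
            if not 0.0 <= self.pi(task) <= 1.0:
                raise ValueError("signal strength must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, recoverable by document id."""

    labels: dict[str, dict[str, str]] = field(default_factory=dict)
    marker_positions: dict[str, list[tuple[int, str]]] = field(
        default_factory=dict
    )
    violations: dict[str, str] = field(default_factory=dict)  # id -> kind
    realized_seizure_mean: float = 0.0
    realized_seizure_sd: float = 0.0
    realized_noise_counts: dict[str, int] = field(default_factory=dict)
    n_noise_opportunities: dict[str, int] = field(default_factory=dict)


# --- seizure-count distribution ----------------------------------------------

@lru_cache(maxsize=8)
def _tuned_count_pmf(
    mean: float, sd: float, low: int, high: int
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Moment-match a truncated negative binomial to (mean, sd) on [low, high].

    Exact truncated moments are computed from the pmf, and (r, mu) are chosen
    on a grid minimizing the squared moment error.  Raises when the targets
    are infeasible under the truncation.
    """
    support = np.arange(low, high + 1)
    if not (low <= mean <= high):
        raise ValueError(
            f"target mean {mean} outside truncation bounds [{low}, {high}]"
        )
    best, best_err = None, np.inf
    for r in np.linspace(0.3, 10.0, 98):
        for mu in np.linspace(max(0.3, mean - 3), mean + 3, 61):
            p = r / (r + mu)
            pmf = stats.nbinom.pmf(support, r, p)
            mass = pmf.sum()
            if mass <= 1e-12:
                continue
            pmf = pmf / mass
            m = float(support @ pmf)
            s = float(math.sqrt(max(0.0, support**2 @ pmf - m * m)))
            err = (m - mean) ** 2 + (s - sd) ** 2
            if err < best_err:
                best, best_err = pmf, err
    if best is None or best_err > 1.0:
        raise ValueError(
            f"cannot match moments mean={mean}, sd={sd} on [{low}, {high}]"
        )
    return tuple(int(k) for k in support), tuple(float(x) for x in best)


def sample_seizure_counts(
    spec: SeizureCountSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    support, pmf = _tuned_count_pmf(spec.mean, spec.sd, spec.low, spec.high)
    return rng.choice(np.array(support), size=n, p=np.array(pmf))


# --- corpus generation --------------------------------------------------------

def _style_profiles(spec: GeneratorSpec, rng: np.random.Generator):
    """Per-clinician multiplicative perturbations of the lemma weights."""
    base = 1.0 / (np.arange(len(spec.background_vocab)) + 2.0)  # Zipf-ish
    styles = []
    for _ in range(spec.clinician_styles):
        w = base * rng.lognormal(0.0, 0.4, size=len(base))
        styles.append(
            {
                "weights": w / w.sum(),
                "length_scale": float(rng.uniform(0.8, 1.25)),
                "function_rate": float(rng.uniform(0.15, 0.3)),
            }
        )
    return styles


def _misspell(token: str, rng: np.random.Generator) -> str:
    if len(token) < 4:
        return token
    i = int(rng.integers(0, len(token) - 1))
    return token[:i] + token[i + 1] + token[i] + token[i + 2 :]


def _assign_labels(rng: np.random.Generator) -> dict[str, str]:
    labels = {
        "side": "left" if rng.random() < _P_LEFT else "right",
        "localization": "temporal" if rng.random() < _P_TEMPORAL
        else "extra_temporal",
    }
    if labels["localization"] == "extra_temporal":
        labels["sublocalization"] = (
            "frontal" if rng.random() < _P_FRONTAL else "posterior"
        )
    return labels


def generate_corpus(spec: GeneratorSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled seizure-description corpus (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    styles = _style_profiles(spec, rng)
    vocab = np.array(spec.background_vocab)
    rates = dict(spec.noise_rates)
    truth = GroundTruth()
    noise_counts = {k: 0 for k in rates}
    opportunities = {k: 0 for k in rates}

    counts = sample_seizure_counts(spec.seizure_counts, spec.n_patients, rng)
    docs: list[RawDocument] = []
    for p in range(spec.n_patients):
        patient_id = f"pat{p:04d}"
        labels = _assign_labels(rng)
        for s in range(int(counts[p])):
            doc_id = f"{patient_id}_sz{s:02d}"
            style = styles[int(rng.integers(0, len(styles)))]
            mean_len = spec.doc_length.mean * style["length_scale"]
            if rng.random() < spec.short_doc_fraction:
                length = int(rng.integers(5, 15))
            else:
                length = max(
                    spec.doc_length.minimum,
                    int(rng.poisson(max(1.0, mean_len
                                        - spec.doc_length.minimum)))
                    + spec.doc_length.minimum,
                )
            tokens = list(rng.choice(vocab, size=length, p=style["weights"]))
            # prose-like filler, stripped later by the stop-word filter
            n_func = int(style["function_rate"] * length)
            for _ in range(n_func):
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, FUNCTION_WORDS[
                    int(rng.integers(0, len(FUNCTION_WORDS)))])

            planted: list[tuple[int, str]] = []
            for task, (_, _) in _TASK_CLASSES.items():
                label = labels.get(task)
                if label is None:
                    continue
                markers = spec.marker_vocab.get(label, ())
                if not markers:
                    continue
                n_markers = int(rng.binomial(spec.marker_slots, spec.pi(task)))
                for _ in range(n_markers):
                    lemma = markers[int(rng.integers(0, len(markers)))]
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens.insert(pos, lemma)
                    planted.append((pos, lemma))

            # raw-text noise
            if rng.random() < rates.get("abbreviation_rate", 0.0):
                noise_counts["abbreviation_rate"] += 1
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, _ABBREVIATIONS[
                    int(rng.integers(0, len(_ABBREVIATIONS)))])
            mis_rate = rates.get("misspelling_rate", 0.0)
            for i, tok in enumerate(tokens):
                opportunities["misspelling_rate"] += 1
                if rng.random() < mis_rate:
                    noise_counts["misspelling_rate"] += 1
                    tokens[i] = _misspell(tok, rng)

            raw_tokens = list(tokens)
            if rng.random() < rates.get("date_rate", 0.0):
                noise_counts["date_rate"] += 1
                raw_tokens.insert(
                    int(rng.integers(0, len(raw_tokens) + 1)),
                    _DATE_TOKENS[int(rng.integers(0, len(_DATE_TOKENS)))],
                )
            if rng.random() < rates.get("bracket_rate", 0.0):
                noise_counts["bracket_rate"] += 1
                raw_tokens.insert(
                    int(rng.integers(0, len(raw_tokens) + 1)),
                    _BRACKET_SNIPPETS[
                        int(rng.integers(0, len(_BRACKET_SNIPPETS)))],
                )
            if rng.random() < rates.get("electrode_rate", 0.0):
                noise_counts["electrode_rate"] += 1
                raw_tokens.insert(
                    int(rng.integers(0, len(raw_tokens) + 1)),
                    "elettrodo " + _ELECTRODE_TOKENS[
                        int(rng.integers(0, len(_ELECTRODE_TOKENS)))],
                )
            for key in ("date_rate", "bracket_rate", "electrode_rate",
                        "abbreviation_rate"):
                opportunities[key] += 1

            text = _render_prose(raw_tokens, rng)
            docs.append(
                RawDocument(
                    doc_id=doc_id,
                    patient_id=patient_id,
                    text=text,
                    doc_kind="seizure",
                    labels=labels,
                )
            )
            truth.labels[doc_id] = dict(labels)
            truth.marker_positions[doc_id] = planted

    realized = counts.astype(float)
    truth.realized_seizure_mean = float(realized.mean())
    truth.realized_seizure_sd = float(realized.std(ddof=1))
    truth.realized_noise_counts = noise_counts
    truth.n_noise_opportunities = opportunities
    corpus = Corpus(
        docs,
        provenance=f"ezloc.synthetic generate_corpus(seed={spec.seed})",
        seed=spec.seed,
    )
    return corpus, truth


def _render_prose(tokens: Sequence[str], rng: np.random.Generator) -> str:
    """Join tokens into sentence-like prose with punctuation and casing."""
    parts: list[str] = []
    start = True
    since_period = 0
    for tok in tokens:
        word = tok.capitalize() if start else tok
        start = False
        since_period += 1
        if since_period >= int(rng.integers(7, 13)):
            parts.append(word + ".")
            start = True
            since_period = 0
        elif rng.random() < 0.08:
            parts.append(word + ",")
        else:
            parts.append(word)
    text = " ".join(parts)
    if not text.endswith("."):
        text += "."
    return text


def generate_emr_corpus(spec: GeneratorSpec, n_docs: int) -> Corpus:
    """Unlabeled EMR-style documents: longer (5-20x a seizure description),
    full-sentence prose over the shared background vocabulary, and free of
    class-marker lemmas (emulating the removal of conclusion sections that
    would reveal the EZ location)."""
    rng = np.random.default_rng((spec.seed, 7001))
    styles = _style_profiles(spec, rng)
    vocab = np.array(spec.background_vocab)
    docs: list[RawDocument] = []
    for d in range(n_docs):
        style = styles[int(rng.integers(0, len(styles)))]
        length = int(spec.doc_length.mean * rng.uniform(5.0, 20.0))
        tokens = list(rng.choice(vocab, size=length, p=style["weights"]))
        n_func = int(0.35 * length)  # anamnestic prose is function-word heavy
        for _ in range(n_func):
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens.insert(pos, FUNCTION_WORDS[
                int(rng.integers(0, len(FUNCTION_WORDS)))])
        docs.append(
            RawDocument(
                doc_id=f"emr{d:04d}",
                patient_id=f"emrpat{d:04d}",
                text=_render_prose(tokens, rng),
                doc_kind="emr",
            )
        )
    return Corpus(
        docs,
        provenance=f"ezloc.synthetic generate_emr_corpus(seed={spec.seed})",
        seed=spec.seed,
    )


# --- planted filter violations ------------------------------------------------

_REFERENCE_SENTENCE = "Crisi simile alle precedenti."


def plant_filter_violations(
    corpus: Corpus, n_short: int, n_reference: int, seed: int
) -> tuple[Corpus, GroundTruth]:
    """Rewrite chosen seizure documents to violate the exclusion filters.

    ``n_short`` documents are truncated below 20 post-cleaning tokens;
    ``n_reference`` documents get a previous-seizure reference sentence
    appended.  Ground truth records which documents were touched.
    """
    seizure_ids = [d.doc_id for d in corpus if d.doc_kind == "seizure"]
    if n_short + n_reference > len(seizure_ids):
        raise ValueError("corpus too small for the requested violations")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(seizure_ids), size=n_short + n_reference,
                        replace=False)
    short_ids = {seizure_ids[i] for i in chosen[:n_short]}
    reference_ids = {seizure_ids[i] for i in chosen[n_short:]}

    truth = GroundTruth()
    new_docs: list[RawDocument] = []
    for doc in corpus:
        if doc.doc_id in short_ids:
            words = [w for w in doc.text.split() if w][:10]
            new_docs.append(replace(doc, text=" ".join(words) or "Crisi breve."))
            truth.violations[doc.doc_id] = "short"
        elif doc.doc_id in reference_ids:
            new_docs.append(replace(doc, text=doc.text + " " +
                                    _REFERENCE_SENTENCE))
            truth.violations[doc.doc_id] = "reference"
        else:
            new_docs.append(doc)
    return (
        Corpus(new_docs, provenance=corpus.provenance, seed=corpus.seed),
        truth,
    )


# --- planted analogy geometry ---------------------------------------------------

ANALOGY_QUERY = ("tavolo", "tavolino", "quadro", "quadrino")  # a, a*, b, b*


def generate_analogy_corpus(
    seed: int, n_sentences: int = 600
) -> Corpus:
    """Tiny corpus planting additive analogy geometry via shared contexts.

    Four target words are defined by the cross of a *base* context (A or B)
    and a *relation* context (plain or diminutive): tavolo = A+plain,
    tavolino = A+star, quadro = B+plain, quadrino = B+star.  Each sentence
    surrounds one target with words drawn from its base and relation context
    sets, so skip-gram training factors the vectors additively and
    ``tavolino - tavolo + quadro`` lands on ``quadrino``.
    """
    base_ctx = {
        "A": ("legno", "arredo", "stanza", "cucina"),
        "B": ("muro", "arte", "colore", "cornice"),
    }
    rel_ctx = {
        "plain": ("grande", "massiccio", "robusto"),
        "star": ("piccolo", "minuto", "grazioso"),
    }
    targets = {
        ("A", "plain"): "tavolo",
        ("A", "star"): "tavolino",
        ("B", "plain"): "quadro",
        ("B", "star"): "quadrino",
    }
    rng = np.random.default_rng(seed)
    keys = list(targets)
    docs: list[RawDocument] = []
    for i in range(n_sentences):
        base, rel = keys[int(rng.integers(0, len(keys)))]
        words = [
            base_ctx[base][int(rng.integers(0, 4))],
            rel_ctx[rel][int(rng.integers(0, 3))],
            targets[(base, rel)],
            base_ctx[base][int(rng.integers(0, 4))],
            rel_ctx[rel][int(rng.integers(0, 3))],
        ]
        docs.append(
            RawDocument(
                doc_id=f"ana{i:04d}",
                patient_id=f"anapat{i:04d}",
                text=" ".join(words),
                doc_kind="emr",
            )
        )
    return Corpus(docs, provenance=f"analogy geometry (seed={seed})", seed=seed)
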