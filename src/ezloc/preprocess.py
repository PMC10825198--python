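"""Text normalization and corpus-level exclusion filters.

The normalization chain applied to every document has four steps:

1. *cleaning* — bracketed spans deleted, whitespace-delimited tokens that
   contain a digit deleted (dates, times, electrode names such as "B2"),
   remaining punctuation replaced by spaces, clinical abbreviations expanded
   ("aass" -> "arti superiori"), output lowercased with collapsed whitespace;
2. *tokenization* — whitespace split;
3. *lemmatization* — dictionary lookup with identity fallback for unknown
   surface forms (the lemma lexicon is a pluggable plain-text resource);
4. *stop-word removal* — closed-class Italian words carry no localizing
   information and are dropped.

Two corpus-level exclusion filters mirror editorial curation of seizure
descriptions: documents shorter than 20 tokens after cleaning, and documents
that merely refer back to previous seizures ("crisi simile alle precedenti")
instead of describing one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus, RawDocument, RunLog, TokenDocument

_BRACKET_RE = re.compile(r"\([^()]*\)|\[[^\[\]]*\]|\{[^{}]*\}")
_DIGIT_RE = re.compile(r"\d")
_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def _read_lines(path: Path) -> list[str]:
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@dataclass
class NormalizationResources:
    """Pluggable language resources for the normalization chain.

    Abbreviation keys are matched case-insensitively and only at word
    boundaries; expansions must themselves be clean text (no digits,
    punctuation or further abbreviations) so that cleaning is idempotent.
    """

    abbreviation_map: dict[str, str] = field(default_factory=dict)
    stoplist: set[str] = field(default_factory=set)
    lemma_lexicon: dict[str, str] = field(default_factory=dict)

    _abbrev_re: re.Pattern | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.abbreviation_map = {
            k.lower(): v.lower() for k, v in self.abbreviation_map.items()
        }
        if self.abbreviation_map:
            alternation = "|".join(
                re.escape(k) for k in sorted(self.abbreviation_map, key=len,
                                             reverse=True)
            )
            self._abbrev_re = re.compile(
                rf"\b(?:{alternation})\b", flags=re.IGNORECASE
            )

    def expand_abbreviations(self, text: str) -> str:
        if self._abbrev_re is None:
            return text
        return self._abbrev_re.sub(
            lambda m: self.abbreviation_map[m.group(0).lower()], text
        )

    @classmethod
    def default(cls) -> "NormalizationResources":
        """Load the resources shipped with the package."""
        root = importlib_resources.files("ezloc") / "resources"
        return cls.from_paths(
            abbreviations=Path(str(root / "abbreviations.tsv")),
            stopwords=Path(str(root / "stopwords_it.txt")),
            lemmas=Path(str(root / "lemmas_it.tsv")),
        )

    @classmethod
    def from_paths(
        cls,
        abbreviations: str | Path | None = None,
        stopwords: str | Path | None = None,
        lemmas: str | Path | None = None,
    ) -> "NormalizationResources":
        abbrev: dict[str, str] = {}
        if abbreviations is not None:
            for line in _read_lines(Path(abbreviations)):
                key, _, expansion = line.partition("\t")
                abbrev[key.strip()] = expansion.strip()
        stop = set(_read_lines(Path(stopwords))) if stopwords else set()
        lex: dict[str, str] = {}
        if lemmas is not None:
            for line in _read_lines(Path(lemmas)):
                surface, _, lemma = line.partition("\t")
                lex[surface.strip()] = lemma.strip()
        return cls(abbreviation_map=abbrev, stoplist=stop, lemma_lexicon=lex)


def clean_text(text: str, resources: NormalizationResources) -> str:
    """Apply the cleaning step (brackets, digit tokens, punctuation,
    abbreviation expansion, lowercasing)."""
    # bracketed spans first, so punctuation removal cannot orphan delimiters;
    # repeat to unwrap nesting
    prev = None
    while prev != text:
        prev = text
        text = _BRACKET_RE.sub(" ", text)
    # any whitespace token containing a digit is a date/time/electrode pattern
    text = " ".join(tok for tok in text.split() if not _DIGIT_RE.search(tok))
    text = _PUNCT_RE.sub(" ", text)
    text = resources.expand_abbreviations(text)
    return _WS_RE.sub(" ", text).strip().lower()


def tokenize(cleaned: str) -> list[str]:
    """Whitespace split of cleaned text; never yields empty tokens."""
    return cleaned.split()


def lemmatize(tokens: Sequence[str], resources: NormalizationResources) -> list[str]:
    """Map each token through the lemma lexicon (identity fallback)."""
    lex = resources.lemma_lexicon
    return [lex.get(tok, tok) for tok in tokens]


def remove_stopwords(
    lemmas: Sequence[str], resources: NormalizationResources
) -> list[str]:
    stop = resources.stoplist
    return [lem for lem in lemmas if lem not in stop]


def preprocess_document(
    doc: RawDocument, resources: NormalizationResources
) -> TokenDocument:
    """Full normalization chain raw text -> TokenDocument."""
    lemmas = remove_stopwords(
        lemmatize(tokenize(clean_text(doc.text, resources)), resources), resources
    )
    return TokenDocument(
        doc_id=doc.doc_id,
        patient_id=doc.patient_id,
        tokens=tuple(lemmas),
        doc_kind=doc.doc_kind,
        labels=dict(doc.labels),
    )


def preprocess_corpus(
    corpus: Corpus | Iterable[RawDocument],
    resources: NormalizationResources,
    log: RunLog | None = None,
) -> list[TokenDocument]:
    docs = list(corpus)
    out = [preprocess_document(d, resources) for d in docs]
    if log is not None:
        log.stage(
            "preprocess",
            "clean/tokenize/lemmatize/stopword chain",
            n_input=len(docs),
            n_output=len(out),
        )
    return out


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_excluded_short: int
    n_excluded_reference: int
    n_retained: int
    excluded_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_input != (
            self.n_retained + self.n_excluded_short + self.n_excluded_reference
        ):
            raise ValueError("filter report does not reconcile")


#: previous-seizure references are flagged when all lemmas of a pattern
#: co-occur in a document ("crisi simile alle precedenti" and variants)
DEFAULT_REFERENCE_PATTERNS: tuple[tuple[str, ...], ...] = (("simile", "precedente"),)


def filter_corpus(
    corpus: Corpus,
    resources: NormalizationResources | None = None,
    min_tokens: int = 20,
    reference_patterns: Sequence[Sequence[str]] = DEFAULT_REFERENCE_PATTERNS,
    log: RunLog | None = None,
) -> tuple[Corpus, FilterReport]:
    """Exclude too-short and previous-reference seizure descriptions.

    The token count is measured after cleaning and tokenization but before
    stop-word removal.  A document failing both checks is counted once, as
    short.  EMR documents are never filtered.  Every exclusion is recorded in
    the report for review.
    """
    if resources is None:
        resources = NormalizationResources.default()
    patterns = [frozenset(p) for p in reference_patterns]
    retained: list[RawDocument] = []
    short_ids: list[str] = []
    reference_ids: list[str] = []
    for doc in corpus:
        if doc.doc_kind != "seizure":
            retained.append(doc)
            continue
        tokens = tokenize(clean_text(doc.text, resources))
        if len(tokens) < min_tokens:
            short_ids.append(doc.doc_id)
            continue
        lemmas = frozenset(lemmatize(tokens, resources))
        if any(pat <= lemmas for pat in patterns):
            reference_ids.append(doc.doc_id)
            continue
        retained.append(doc)
    report = FilterReport(
        n_input=len(corpus),
        n_excluded_short=len(short_ids),
        n_excluded_reference=len(reference_ids),
        n_retained=len(retained),
        excluded_ids=tuple(short_ids + reference_ids),
    )
    if log is not None:
        log.stage(
            "filter_corpus",
            "short/previous-reference exclusion",
            n_input=report.n_input,
            n_excluded_short=report.n_excluded_short,
            n_excluded_reference=report.n_excluded_reference,
            n_retained=report.n_retained,
        )
    filtered = Corpus(retained, provenance=corpus.provenance, seed=corpus.seed)
    return filtered, report
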