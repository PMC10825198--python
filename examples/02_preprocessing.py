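"""Normalize one noisy clinical sentence step by step.

Shows the cleaning rules (bracketed spans, digit-bearing tokens such as times
and electrode names, punctuation, abbreviation expansion), then tokenization,
dictionary lemmatization and stop-word removal.
"""

from ezloc import (
    NormalizationResources,
    clean_text,
    lemmatize,
    remove_stopwords,
    tokenize,
)

resources = NormalizationResources.default()
raw = "Il paziente apre gli occhi alle 14:30 (elettrodo B2); aass tonici."
print("raw:      ", raw)

cleaned = clean_text(raw, resources)
print("cleaned:  ", cleaned)  # brackets/digits/punctuation gone, aass expanded

tokens = tokenize(cleaned)
lemmas = lemmatize(tokens, resources)
print("lemmas:   ", lemmas)  # apre -> aprire, occhi -> occhio, ...

content = remove_stopwords(lemmas, resources)
print("content:  ", content)  # articles and prepositions dropped
# Only the content lemmas feed the bag-of-words and embedding representations.
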