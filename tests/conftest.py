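import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ezloc import NormalizationResources, TokenDocument
from ezloc.corpus import EmbeddingParams
from ezloc.embedding import EmbeddingModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def resources() -> NormalizationResources:
    return NormalizationResources.default()


def make_model(vectors: dict[str, list[float]]) -> EmbeddingModel:
    """EmbeddingModel with hand-planted vectors (for evaluator tests)."""
    words = tuple(vectors)
    mat = np.array([vectors[w] for w in words], dtype=np.float64)
    return EmbeddingModel(
        vocabulary=words,
        vectors=mat,
        params=EmbeddingParams(dimension=mat.shape[1]),
    )


def make_doc(tokens, doc_id="d0", patient_id="p0", labels=None) -> TokenDocument:
    return TokenDocument(
        doc_id=doc_id,
        patient_id=patient_id,
        tokens=tuple(tokens),
        labels=labels or {},
    )
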