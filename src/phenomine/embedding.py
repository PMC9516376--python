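"""Document-embedding backends: truncation, hierarchical mean pooling, hash n-grams.

Three strategies produce a fixed-dimension vector per document:

``hash_ngram``
    Character 1–3-gram counts hashed into a fixed number of buckets and
    L2-normalized.  Deterministic, needs no external model; the default
    backend for tests and offline runs.
``truncate_encoder``
    Keep the first ``max_tokens`` tokens and pass one block through an
    external pretrained sentence encoder (resolved by id from a registry).
    Length-limited contextual encoders see only the head of the document,
    which is why key-sentence selection matters upstream.
``hierarchy_mean``
    Encode each sentence separately (each truncated to ``max_tokens``) and
    average the sentence vectors — the unweighted-mean flavour of
    hierarchical document representation.

External encoders are never bundled: an unknown ``encoder_id`` raises
``EncoderUnavailableError`` rather than silently falling back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import HashingVectorizer

from .segmentation import split_sentences

BACKENDS = ("truncate_encoder", "hierarchy_mean", "hash_ngram")


class EncoderUnavailableError(RuntimeError):
    """Raised when an encoder_id cannot be resolved to a usable encoder."""


class SentenceEncoder(Protocol):
    dim: int

    def encode(self, texts: list[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class EmbedderConfig:
    backend: str = "hash_ngram"
    encoder_id: str = "hash-ngram"
    max_tokens: int = 512
    dim: int = 1024

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.max_tokens < 1 or self.dim < 1:
            raise ValueError("max_tokens and dim must be >= 1")


@dataclass
class DocumentVector:
    doc_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite embedding for {self.doc_id!r}")


class HashNgramEncoder:
    """Deterministic character n-gram hashing encoder (the built-in backend)."""

    def __init__(self, dim: int = 1024, ngram_range: tuple[int, int] = (1, 3)):
        self.dim = dim
        self._vectorizer = HashingVectorizer(
            analyzer="char",
            ngram_range=ngram_range,
            n_features=dim,
            norm="l2",
            alternate_sign=False,
            lowercase=False,
        )

    def encode(self, texts: list[str]) -> np.ndarray:
        if not texts:
            return np.zeros((0, self.dim))
        return np.asarray(self._vectorizer.transform(texts).todense())


_ENCODER_REGISTRY: dict[str, Callable[..., SentenceEncoder]] = {
    "hash-ngram": HashNgramEncoder,
}


def register_encoder(encoder_id: str, factory: Callable[..., SentenceEncoder]) -> None:
    """Register an external encoder factory under an id string."""
    _ENCODER_REGISTRY[encoder_id] = factory


def resolve_encoder(encoder_id: str, dim: int | None = None) -> SentenceEncoder:
    """Resolve an encoder id; ``"hash-ngram:256"`` selects the bucket count."""
    name, _, arg = encoder_id.partition(":")
    factory = _ENCODER_REGISTRY.get(name)
    if factory is None:
        raise EncoderUnavailableError(
            f"no encoder registered under {encoder_id!r}; register one with "
            "phenomine.embedding.register_encoder"
        )
    if name == "hash-ngram":
        return factory(dim=int(arg) if arg else (dim or 1024))
    return factory()


def _truncate(text: str, max_tokens: int, language: str) -> str:
    if language == "en":
        return " ".join(text.split()[:max_tokens])
    return text[:max_tokens]


class TruncatingEncoderVectorizer(TransformerMixin, BaseEstimator):
    """Embed the first ``max_tokens`` tokens of each document with an encoder."""

    def __init__(self, encoder_id: str = "hash-ngram", max_tokens: int = 512,
                 language: str = "zh", dim: int = 1024):
        self.encoder_id = encoder_id
        self.max_tokens = max_tokens
        self.language = language
        self.dim = dim

    def fit(self, X, y=None):
        self.encoder_ = resolve_encoder(self.encoder_id, dim=self.dim)
        self.dim_ = self.encoder_.dim
        return self

    def transform(self, X) -> np.ndarray:
        encoder = getattr(self, "encoder_", None) or resolve_encoder(self.encoder_id, dim=self.dim)
        blocks = [_truncate(t, self.max_tokens, self.language) for t in X]
        out = encoder.encode(blocks)
        if not np.all(np.isfinite(out)):
            raise ValueError("encoder produced non-finite values")
        return out


class MeanSentenceVectorizer(TransformerMixin, BaseEstimator):
    """Hierarchical representation: mean of per-sentence encoder vectors."""

    def __init__(self, encoder_id: str = "hash-ngram", max_tokens: int = 512,
                 language: str = "zh", dim: int = 1024):
        self.encoder_id = encoder_id
        self.max_tokens = max_tokens
        self.language = language
        self.dim = dim

    def fit(self, X, y=None):
        self.encoder_ = resolve_encoder(self.encoder_id, dim=self.dim)
        self.dim_ = self.encoder_.dim
        return self

    def transform(self, X) -> np.ndarray:
        encoder = getattr(self, "encoder_", None) or resolve_encoder(self.encoder_id, dim=self.dim)
        rows = []
        for text in X:
            sentences = [
                _truncate(t, self.max_tokens, self.language)
                for t in split_sentences(text, self.language).texts
            ]
            if not sentences:
                rows.append(np.zeros(encoder.dim))
                continue
            rows.append(encoder.encode(sentences).mean(axis=0))
        out = np.vstack(rows) if rows else np.zeros((0, encoder.dim))
        if not np.all(np.isfinite(out)):
            raise ValueError("encoder produced non-finite values")
        return out


class HashNgramVectorizer(TransformerMixin, BaseEstimator):
    """Whole-document hashed character n-gram embedding (offline backend)."""

    def __init__(self, dim: int = 1024, ngram_range: tuple[int, int] = (1, 3)):
        self.dim = dim
        self.ngram_range = ngram_range

    def fit(self, X, y=None):
        self.encoder_ = HashNgramEncoder(dim=self.dim, ngram_range=self.ngram_range)
        self.dim_ = self.dim
        return self

    def transform(self, X) -> np.ndarray:
        encoder = getattr(self, "encoder_", None) or HashNgramEncoder(
            dim=self.dim, ngram_range=self.ngram_range
        )
        return encoder.encode(list(X))


def make_vectorizer(config: EmbedderConfig, language: str = "zh"):
    """Build the transformer matching an :class:`EmbedderConfig`."""
    if config.backend == "hash_ngram":
        return HashNgramVectorizer(dim=config.dim)
    if config.backend == "truncate_encoder":
        return TruncatingEncoderVectorizer(
            encoder_id=config.encoder_id, max_tokens=config.max_tokens,
            language=language, dim=config.dim,
        )
    return MeanSentenceVectorizer(
        encoder_id=config.encoder_id, max_tokens=config.max_tokens,
        language=language, dim=config.dim,
    )


def embed_truncated(text: str, config: EmbedderConfig, doc_id: str = "",
                    language: str = "zh") -> DocumentVector:
    vec = TruncatingEncoderVectorizer(
        encoder_id=config.encoder_id, max_tokens=config.max_tokens,
        language=language, dim=config.dim,
    ).fit([]).transform([text])[0]
    return DocumentVector(doc_id=doc_id, values=vec)


def embed_hierarchy_mean(text: str, config: EmbedderConfig, doc_id: str = "",
                         language: str = "zh") -> DocumentVector:
    vec = MeanSentenceVectorizer(
        encoder_id=config.encoder_id, max_tokens=config.max_tokens,
        language=language, dim=config.dim,
    ).fit([]).transform([text])[0]
    return DocumentVector(doc_id=doc_id, values=vec)


def embed_hash_ngram(text: str, config: EmbedderConfig, doc_id: str = "") -> DocumentVector:
    vec = HashNgramVectorizer(dim=config.dim).fit([]).transform([text])[0]
    return DocumentVector(doc_id=doc_id, values=vec)
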