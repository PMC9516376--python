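"""End-to-end phenotyping pipeline: select → embed → classify.

The pipeline bundles a key-sentence selector (optional — omit it to classify
original text), an embedding transformer and a grid-searched classifier,
together with the label scheme, so a single fitted object can be persisted
and later applied to an archive stream.
"""

from __future__ import annotations

import hashlib

import joblib
from sklearn.base import BaseEstimator

from .classify import GridSearchTextClassifier
from .corpus import LabeledCorpus, LabelScheme
from .embedding import HashNgramVectorizer
from .selection import KeySentenceSelector


def keywords_hash(terms) -> str:
    """Stable fingerprint of a keyword list, recorded in the model bundle."""
    digest = hashlib.sha256("\n".join(terms).encode("utf-8")).hexdigest()
    return digest[:16]


class PhenotypePipeline(BaseEstimator):
    """Selector + vectorizer + classifier over one label scheme.

    Parameters mirror the stage estimators; ``selector=None`` classifies the
    original text (the truncation/hierarchy baselines do their own length
    handling inside the vectorizer).
    """

    def __init__(
        self,
        scheme: LabelScheme,
        selector: KeySentenceSelector | None = None,
        vectorizer=None,
        classifier: GridSearchTextClassifier | None = None,
    ):
        self.scheme = scheme
        self.selector = selector
        self.vectorizer = vectorizer
        self.classifier = classifier

    def _stages(self):
        vectorizer = self.vectorizer if self.vectorizer is not None else HashNgramVectorizer()
        classifier = self.classifier if self.classifier is not None else GridSearchTextClassifier()
        return vectorizer, classifier

    def fit(self, corpus: LabeledCorpus):
        texts = corpus.texts
        labels = corpus.labels
        if any(l is None for l in labels):
            raise ValueError("every training document must be labeled")
        if self.selector is not None:
            self.selector.fit(texts)
            texts = self.selector.transform(texts)
        self.vectorizer_, self.classifier_ = self._stages()
        X = self.vectorizer_.fit(texts).transform(texts)
        self.classifier_.fit(X, labels)
        if self.selector is not None:
            self.keywords_hash_ = keywords_hash(self.selector.keywords_.terms)
        return self

    def transform_texts(self, texts: list[str]) -> list[str]:
        if self.selector is not None:
            return self.selector.transform(texts)
        return list(texts)

    def predict_texts(self, texts: list[str]) -> list[str]:
        selected = self.transform_texts(texts)
        X = self.vectorizer_.transform(selected)
        return list(self.classifier_.predict(X))

    def predict_corpus(self, corpus: LabeledCorpus) -> list[str]:
        return self.predict_texts(corpus.texts)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PhenotypePipeline":
        model = joblib.load(path)
        if not isinstance(model, PhenotypePipeline):
            raise TypeError(f"{path} does not contain a PhenotypePipeline")
        return model
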