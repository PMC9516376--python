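"""Key-sentence selection and the keyword oracle.

Selection keeps exactly the sentences that contain a task keyword, in
original order.  Long visit documents shrink to a handful of evidence
sentences, short enough for any length-limited embedding backend.

The *oracle test* bounds what selection can cost: predict each document's
gold tag if it contains any keyword and the fallback tag otherwise, then
score micro-F1 against gold.  A score of 1.0 means the keyword list loses no
document that carries evidence; shortfall measures keyword-free positives.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import Document, LabeledCorpus
from .keywords import KeywordList, contains_keyword, load_builtin_keywords
from .segmentation import length_stats, split_sentences


@dataclass
class SelectedDocument:
    doc_id: str
    selected_text: str
    kept_indices: list[int]
    n_sentences_total: int


def _join(texts: list[str], language: str) -> str:
    return (" " if language == "en" else "").join(texts)


def select_key_sentences(doc: Document, keywords: KeywordList) -> SelectedDocument:
    """Keep exactly the sentences of ``doc`` that contain a keyword."""
    sentence_list = split_sentences(doc.text, doc.language)
    kept = [(i, t) for i, t in sentence_list.sentences if contains_keyword(t, keywords)]
    return SelectedDocument(
        doc_id=doc.doc_id,
        selected_text=_join([t for _, t in kept], doc.language),
        kept_indices=[i for i, _ in kept],
        n_sentences_total=len(sentence_list),
    )


def select_text(text: str, keywords: KeywordList, language: str) -> str:
    kept = [
        t for _, t in split_sentences(text, language).sentences
        if contains_keyword(t, keywords)
    ]
    return _join(kept, language)


class KeySentenceSelector(TransformerMixin, BaseEstimator):
    """Transformer mapping raw texts to their keyword-bearing sentences.

    Parameters
    ----------
    keywords : KeywordList or str
        A keyword list, or the name of a built-in one (``"smoking"``,
        ``"dhr_guideline"``).
    language : {"zh", "en"}
        Sentence-splitting and joining convention.
    """

    def __init__(self, keywords="dhr_guideline", language: str = "zh"):
        self.keywords = keywords
        self.language = language

    def _resolve(self) -> KeywordList:
        if isinstance(self.keywords, str):
            return load_builtin_keywords(self.keywords)
        return self.keywords

    def fit(self, X, y=None):  # stateless; selection needs no fitting
        self.keywords_ = self._resolve()
        return self

    def transform(self, X) -> list[str]:
        kw = getattr(self, "keywords_", None) or self._resolve()
        return [select_text(text, kw, self.language) for text in X]


def oracle_test(corpus: LabeledCorpus, keywords: KeywordList) -> float:
    """Micro-F1 of the keyword-presence oracle against gold labels.

    The oracle predicts a document's gold tag when any of its sentences
    contains a keyword and the scheme's fallback label otherwise — including
    for fallback-labeled documents that do contain a keyword, whose gold tag
    is the fallback anyway.  Errors therefore come only from keyword-free
    positives.
    """
    from .classify import micro_f1

    gold: list[str] = []
    pred: list[str] = []
    fallback = corpus.scheme.fallback_label
    for doc in corpus.documents:
        if doc.label is None:
            raise ValueError(f"document {doc.doc_id!r} is unlabeled")
        has_kw = any(
            contains_keyword(t, keywords)
            for t in split_sentences(doc.text, doc.language).texts
        )
        gold.append(doc.label)
        pred.append(doc.label if has_kw else fallback)
    return micro_f1(gold, pred)


def selection_report(corpus: LabeledCorpus, keywords: KeywordList) -> dict:
    """Length statistics of original vs selected text plus the oracle score.

    Returns a dict shaped like the corpus-statistics tables: per text variant
    the maximum and (integer-rounded) mean unit count, and the oracle
    micro-F1 for the selected variant.
    """
    language = corpus.documents[0].language if corpus.documents else "zh"
    selected = [select_key_sentences(d, keywords).selected_text for d in corpus.documents]
    orig_max, orig_mean = length_stats(corpus.texts, language, rounded=True)
    sel_max, sel_mean = length_stats(selected, language, rounded=True)
    return {
        "original": {"max_units": orig_max, "mean_units": orig_mean},
        "selected": {"max_units": sel_max, "mean_units": sel_mean},
        "oracle_micro_f1": oracle_test(corpus, keywords),
        "n_documents": len(corpus.documents),
    }
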