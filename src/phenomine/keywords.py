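"""Keyword lists and discriminative TF-IDF keyword derivation.

Two built-in lists ship with the package: the seven smoking-status unigrams
(``cigarette, smoke, smoked, smoker, smokes, smoking, tobacco``) and the
Chinese guideline terms for the four severe drug hypersensitivity reaction
subtypes (disease names and abbreviations, symptom terms, and the treatment
drugs).  A third kind of list is derived from a training corpus by TF-IDF:
take the top candidate terms by weight, drop anything with digits,
out-of-script letters or punctuation, then keep terms whose mean TF-IDF in
positive documents exceeds that in fallback documents.

Matching conventions differ by script: Chinese keywords match as contiguous
substrings (Chinese has no word delimiters); English keywords match whole
tokens, case-insensitively, so ``smoke`` does not fire inside ``smokescreen``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import LabeledCorpus

PROVENANCES = ("builtin_guideline", "builtin_smoking", "tfidf_derived")
MATCH_MODES = ("substring", "word_boundary")

_BUILTIN_FILES = {
    "smoking": ("smoking_en.txt", "builtin_smoking", "word_boundary"),
    "dhr_guideline": ("dhr_guideline_zh.txt", "builtin_guideline", "substring"),
}


@dataclass(frozen=True)
class KeywordList:
    """Ordered, deduplicated surface strings with provenance and match mode."""

    terms: tuple[str, ...]
    provenance: str
    match_mode: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.match_mode not in MATCH_MODES:
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if any(not t for t in self.terms):
            raise ValueError("empty-string keyword term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate keyword terms")

    @classmethod
    def from_terms(cls, terms, provenance: str, match_mode: str) -> "KeywordList":
        """Build a list, deduplicating while preserving first-occurrence order."""
        seen: dict[str, None] = {}
        for t in terms:
            t = t.strip()
            if t:
                seen.setdefault(t)
        return cls(terms=tuple(seen), provenance=provenance, match_mode=match_mode)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.terms) + "\n")

    @classmethod
    def load(cls, path, provenance: str = "tfidf_derived", match_mode: str = "substring"):
        with open(path, encoding="utf-8") as fh:
            return cls.from_terms(fh.read().splitlines(), provenance, match_mode)


def load_builtin_keywords(task: str) -> KeywordList:
    """Load a packaged keyword list: ``smoking`` or ``dhr_guideline``."""
    try:
        filename, provenance, mode = _BUILTIN_FILES[task]
    except KeyError:
        raise ValueError(
            f"unknown task {task!r}; expected one of {sorted(_BUILTIN_FILES)}"
        ) from None
    text = resources.files("phenomine.data").joinpath(filename).read_text("utf-8")
    return KeywordList.from_terms(text.splitlines(), provenance, mode)


@lru_cache(maxsize=64)
def _compiled(terms: tuple[str, ...], match_mode: str) -> re.Pattern:
    # longer terms first so alternation prefers maximal matches
    ordered = sorted(terms, key=len, reverse=True)
    if match_mode == "substring":
        return re.compile("|".join(re.escape(t) for t in ordered))
    body = "|".join(re.escape(t) for t in ordered)
    return re.compile(rf"(?<!\w)(?:{body})(?!\w)", re.IGNORECASE)


def contains_keyword(sentence: str, keywords: KeywordList) -> bool:
    """True iff any keyword occurs in the sentence under the list's match mode."""
    if not keywords.terms or not sentence:
        return False
    return _compiled(keywords.terms, keywords.match_mode).search(sentence) is not None


def _en_analyzer(text: str) -> list[str]:
    return text.lower().split()


def _zh_analyzer(text: str) -> list[str]:
    chars = [c for c in text if not c.isspace()]
    return chars + ["".join(chars[i : i + 2]) for i in range(len(chars) - 1)]


_CJK = re.compile(r"^[一-鿿]+$")
_ASCII_ALPHA = re.compile(r"^[A-Za-z]+$")


def _term_admissible(term: str, language: str) -> bool:
    """Reject candidate terms with digits, out-of-script letters or punctuation.

    For a Chinese corpus a surviving term consists solely of CJK ideographs;
    for an English corpus, solely of ASCII letters.
    """
    if language == "zh":
        return bool(_CJK.match(term))
    return bool(_ASCII_ALPHA.match(term))


def extract_tfidf_keywords(
    train: LabeledCorpus,
    top_n: int = 2000,
    language: str | None = None,
) -> KeywordList:
    """Derive a discriminative keyword list from a labeled training corpus.

    Procedure: tokenize (en: whitespace tokens; zh: character unigrams and
    bigrams), fit TF-IDF over the training documents, take the ``top_n``
    candidates by maximum TF-IDF weight, drop inadmissible surface forms,
    then score each survivor by its mean TF-IDF in positive-labeled documents
    minus its mean in fallback-labeled documents and keep scores > 0, ordered
    by descending score.
    """
    docs = train.documents
    if language is None:
        language = docs[0].language if docs else "zh"
    labels = [d.label for d in docs]
    fallback = train.scheme.fallback_label
    pos_mask = np.array([l is not None and l != fallback for l in labels])
    neg_mask = np.array([l == fallback for l in labels])
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError(
            "TF-IDF keyword derivation needs at least one positive and one "
            "fallback-labeled document"
        )

    analyzer = _zh_analyzer if language == "zh" else _en_analyzer
    vectorizer = TfidfVectorizer(analyzer=analyzer)
    X = vectorizer.fit_transform(d.text for d in docs)
    vocab = vectorizer.get_feature_names_out()

    max_weight = np.asarray(X.max(axis=0).todense()).ravel()
    candidate_idx = np.argsort(-max_weight, kind="stable")[:top_n]

    pos_mean = np.asarray(X[pos_mask].mean(axis=0)).ravel()
    neg_mean = np.asarray(X[neg_mask].mean(axis=0)).ravel()

    scored: list[tuple[float, int, str]] = []
    for rank, idx in enumerate(candidate_idx):
        term = vocab[idx]
        if not _term_admissible(term, language):
            continue
        score = float(pos_mean[idx] - neg_mean[idx])
        if score > 0:
            scored.append((score, rank, term))
    scored.sort(key=lambda t: (-t[0], t[1]))
    mode = "substring" if language == "zh" else "word_boundary"
    return KeywordList.from_terms((t for _, _, t in scored), "tfidf_derived", mode)
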