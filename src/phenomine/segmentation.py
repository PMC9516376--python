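"""Rule-based sentence splitting and length accounting for clinical text.

Lengths are counted in the unit conventional for each language: whitespace-
delimited tokens for English, non-whitespace characters for Chinese (clinical
Chinese has no word delimiters, so character counts are the stable unit).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

# Terminal punctuation treated as a sentence boundary.  Semicolons are
# boundaries in both languages: clinical notes chain findings with them and
# keyword evidence stays local to the clause.
_TERMINALS = {"zh": "。！？；\n", "en": ".!?;\n"}


@dataclass
class SentenceList:
    """Sentences of one document, in original order with original indices."""

    sentences: list[tuple[int, str]]
    source_doc_id: str = ""

    @property
    def texts(self) -> list[str]:
        return [t for _, t in self.sentences]

    def __len__(self) -> int:
        return len(self.sentences)


def split_sentences(text: str, language: str) -> SentenceList:
    """Split on terminal punctuation (zh: 。！？； en: ``. ! ? ;`` plus newline).

    Each sentence keeps its trailing punctuation; surrounding whitespace is
    stripped and empty fragments dropped, so re-splitting a sentence returns
    itself.
    """
    terminals = _TERMINALS[language]
    if not text:
        return SentenceList(sentences=[])
    cls = re.escape(terminals.replace("\n", "")) + r"\n"
    pattern = re.compile(rf"[^{cls}]*[{cls}]+|[^{cls}]+")
    sentences: list[tuple[int, str]] = []
    index = 0
    for match in pattern.finditer(text):
        fragment = match.group().strip()
        if fragment:
            sentences.append((index, fragment))
            index += 1
    return SentenceList(sentences=sentences)


def count_units(text: str, language: str) -> int:
    """Length of ``text`` in language units (en: tokens; zh: characters)."""
    if language == "en":
        return len(text.split())
    if language == "zh":
        return sum(1 for c in text if not c.isspace())
    raise ValueError(f"unknown language {language!r}")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def length_stats(
    texts: Iterable[str], language: str, rounded: bool = False
) -> tuple[int, float | int]:
    """Maximum and mean unit count over a collection of texts.

    With ``rounded=True`` the mean is rounded half-up to an integer, the
    presentation used in corpus summary tables.
    """
    counts = [count_units(t, language) for t in texts]
    if not counts:
        raise ValueError("length_stats requires a non-empty collection")
    mean = sum(counts) / len(counts)
    return max(counts), (round_half_up(mean) if rounded else mean)
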