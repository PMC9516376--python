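"""Tagged document corpora: data model, JSONL/CSV I/O, stratified splitting, counts.

A *document* is the concatenated free text of one inpatient visit, carrying an
id, a language tag (``zh`` or ``en``) and an optional gold class label.  A
*label scheme* is an ordered class vocabulary with a designated fallback label
— the no-evidence class a keyword-free document defaults to (``NEG`` for the
drug-hypersensitivity task, ``UNKNOWN`` for smoking-status phenotyping).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

LANGUAGES = ("zh", "en")


@dataclass(frozen=True)
class Document:
    """One visit's concatenated clinical notes."""

    doc_id: str
    text: str
    language: str = "zh"
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be a non-empty string")
        if self.language not in LANGUAGES:
            raise ValueError(f"language must be one of {LANGUAGES}, got {self.language!r}")


@dataclass(frozen=True)
class LabelScheme:
    """Ordered class vocabulary with a fallback (no-evidence) label."""

    labels: tuple[str, ...]
    fallback_label: str

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in scheme")
        if self.fallback_label not in self.labels:
            raise ValueError(f"fallback label {self.fallback_label!r} not in labels")

    @property
    def positive_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l != self.fallback_label)


#: Severe drug hypersensitivity reaction scheme: four positive subtypes
#: (Stevens-Johnson syndrome, drug-induced hypersensitivity syndrome,
#: anaphylactic shock, epidermolysis bullosa) plus a negative class.
DHR_SCHEME = LabelScheme(labels=("SJS", "DIHS", "AS", "EB", "NEG"), fallback_label="NEG")

#: Smoking-status scheme (the ambiguous generic "smoker" class is excluded).
SMOKING_SCHEME = LabelScheme(
    labels=("PAST", "CURRENT", "NON", "UNKNOWN"), fallback_label="UNKNOWN"
)

SCHEME_PRESETS: dict[str, LabelScheme] = {"dhr": DHR_SCHEME, "smoking": SMOKING_SCHEME}


@dataclass
class LabeledCorpus:
    """Ordered collection of documents under one label scheme."""

    documents: list[Document]
    scheme: LabelScheme

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)
            if doc.label is not None and doc.label not in self.scheme.labels:
                raise ValueError(
                    f"document {doc.doc_id!r} has label {doc.label!r} "
                    f"outside scheme {self.scheme.labels}"
                )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def texts(self) -> list[str]:
        return [d.text for d in self.documents]

    @property
    def labels(self) -> list[str | None]:
        return [d.label for d in self.documents]


@dataclass
class ClassCounts:
    """Per-label document counts; ``total`` is always their sum."""

    per_label: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_label.values())

    def __getitem__(self, label: str) -> int:
        return self.per_label.get(label, 0)


def class_counts(corpus: LabeledCorpus) -> ClassCounts:
    """Count labeled documents per class (unlabeled documents are skipped)."""
    counts = {label: 0 for label in corpus.scheme.labels}
    for doc in corpus.documents:
        if doc.label is not None:
            counts[doc.label] += 1
    return ClassCounts(per_label=counts)


def _doc_from_record(record: dict, lineno: int, allow_empty_text: bool) -> Document:
    if "doc_id" not in record or "text" not in record:
        raise ValueError(f"record {lineno}: missing doc_id or text field")
    text = record["text"] or ""
    if not text and not allow_empty_text:
        raise ValueError(f"record {lineno} ({record['doc_id']!r}): empty text")
    label = record.get("label") or None
    return Document(
        doc_id=str(record["doc_id"]),
        text=text,
        language=record.get("language", "zh"),
        label=label,
    )


def read_corpus(
    path: str | Path,
    scheme: LabelScheme,
    format: str | None = None,
    strict: bool = True,
) -> LabeledCorpus:
    """Read a tagged corpus from JSONL or CSV.

    JSONL carries one object per line with keys ``doc_id``, ``text``,
    ``language`` and optional ``label``; CSV uses the same column names
    (UTF-8, header row, quoted text column).  In strict mode a record whose
    label is outside the scheme raises; in lenient mode it is dropped with a
    warning and empty texts are tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"

    records: list[tuple[int, dict]] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    records.append((lineno, json.loads(line)))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=1):
                records.append((lineno, row))
    else:
        raise ValueError(f"unknown format {format!r}")

    documents: list[Document] = []
    for lineno, record in records:
        doc = _doc_from_record(record, lineno, allow_empty_text=not strict)
        if doc.label is not None and doc.label not in scheme.labels:
            if strict:
                raise ValueError(
                    f"record {lineno} ({doc.doc_id!r}): unknown label {doc.label!r}"
                )
            logger.warning("dropping %r: label %r outside scheme", doc.doc_id, doc.label)
            continue
        documents.append(doc)
    return LabeledCorpus(documents=documents, scheme=scheme)


def write_corpus(corpus: LabeledCorpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to JSONL or CSV (inverse of :func:`read_corpus`)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {"doc_id": d.doc_id, "text": d.text, "language": d.language, "label": d.label}
        for d in corpus.documents
    ]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["doc_id", "text", "language", "label"], quoting=csv.QUOTE_ALL
            )
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    else:
        raise ValueError(f"unknown format {format!r}")


def split_corpus(
    corpus: LabeledCorpus, test_fraction: float, seed: int
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Stratified train/test split, reproducible for a fixed seed.

    Per-class test counts are apportioned by the largest-remainder rule so
    small classes keep proportions close to ``test_fraction``.  The split is
    an exact partition: no overlap, union equals the input.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_label: dict[str, list[Document]] = {}
    for doc in corpus.documents:
        if doc.label is None:
            raise ValueError(f"document {doc.doc_id!r} is unlabeled; cannot stratify")
        by_label.setdefault(doc.label, []).append(doc)

    too_small = sorted(l for l, docs in by_label.items() if len(docs) < 2)
    if too_small:
        raise ValueError(f"classes with fewer than 2 members cannot be stratified: {too_small}")

    n_total = len(corpus.documents)
    target_total = int(math.floor(n_total * test_fraction + 0.5))
    quotas = {l: len(docs) * test_fraction for l, docs in by_label.items()}
    take = {l: min(int(math.floor(q)), len(by_label[l]) - 1) for l, q in quotas.items()}
    # distribute the remaining seats by largest fractional remainder,
    # ties broken toward larger classes then scheme label order
    order = sorted(
        by_label,
        key=lambda l: (-(quotas[l] - math.floor(quotas[l])), -len(by_label[l]), l),
    )
    remaining = target_total - sum(take.values())
    for label in order:
        if remaining <= 0:
            break
        if take[label] < len(by_label[label]) - 1:
            take[label] += 1
            remaining -= 1

    rng = np.random.default_rng(seed)
    test_ids: set[str] = set()
    for label in sorted(by_label):
        docs = by_label[label]
        idx = rng.permutation(len(docs))[: take[label]]
        test_ids.update(docs[i].doc_id for i in idx)

    train_docs = [d for d in corpus.documents if d.doc_id not in test_ids]
    test_docs = [d for d in corpus.documents if d.doc_id in test_ids]
    return (
        LabeledCorpus(documents=train_docs, scheme=corpus.scheme),
        LabeledCorpus(documents=test_docs, scheme=corpus.scheme),
    )
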