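"""Archive mining: apply a fitted pipeline to an untagged document stream.

Each document is processed independently (select → embed → predict), so the
pass is single-stream with constant memory per document and the output is
invariant to how the stream is chunked.  Only positive-class predictions
become alerts; the alert carries the evidence sentences so a clinician can
confirm or reject the case — expert confirmation is a human step outside
this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .corpus import Document, LabelScheme
from .segmentation import count_units
from .selection import select_key_sentences
from .pipeline import PhenotypePipeline

logger = logging.getLogger(__name__)


@dataclass
class AlertRecord:
    doc_id: str
    predicted_label: str
    evidence: list[str]
    selected_unit_count: int

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "predicted_label": self.predicted_label,
            "evidence": self.evidence,
            "selected_unit_count": self.selected_unit_count,
        }


@dataclass
class MiningSummary:
    n_scanned: int = 0
    per_label: dict[str, int] = field(default_factory=dict)

    @property
    def n_alerted(self) -> int:
        return sum(self.per_label.values())

    def to_dict(self) -> dict:
        return {
            "n_scanned": self.n_scanned,
            "n_alerted": self.n_alerted,
            "per_label": self.per_label,
        }


def mine_archive(
    stream: Iterable[Document],
    model: PhenotypePipeline,
    strict: bool = False,
) -> tuple[list[AlertRecord], MiningSummary]:
    """Scan a document stream and alert on positive-class predictions.

    Malformed documents (no text) are skipped with a warning in lenient mode
    and raise in strict mode.
    """
    positive = set(model.scheme.positive_labels)
    alerts: list[AlertRecord] = []
    summary = MiningSummary(per_label={l: 0 for l in model.scheme.positive_labels})
    for doc in stream:
        if not isinstance(doc, Document) or not doc.text:
            if strict:
                raise ValueError(f"malformed document in stream: {doc!r}")
            logger.warning("skipping malformed document: %r", getattr(doc, "doc_id", doc))
            continue
        summary.n_scanned += 1
        label = model.predict_texts([doc.text])[0]
        if label not in positive:
            continue
        if model.selector is not None:
            selected = select_key_sentences(doc, model.selector.keywords_)
            evidence = _kept_texts(doc, selected)
            unit_count = count_units(selected.selected_text, doc.language)
        else:
            evidence = []
            unit_count = count_units(doc.text, doc.language)
        if not evidence and model.selector is not None:
            logger.warning("alert on empty selection for %r", doc.doc_id)
        alerts.append(
            AlertRecord(
                doc_id=doc.doc_id,
                predicted_label=label,
                evidence=evidence,
                selected_unit_count=unit_count,
            )
        )
        summary.per_label[label] += 1
    return alerts, summary


def _kept_texts(doc: Document, selected) -> list[str]:
    from .segmentation import split_sentences

    sentences = dict(split_sentences(doc.text, doc.language).sentences)
    return [sentences[i] for i in selected.kept_indices]


def summarize_alerts(alerts: list[AlertRecord], scheme: LabelScheme) -> dict[str, int]:
    """Per-positive-label alert counts plus a ``Total`` row equal to their sum."""
    table = {label: 0 for label in scheme.positive_labels}
    for alert in alerts:
        if alert.predicted_label not in table:
            raise ValueError(f"alert with non-positive label {alert.predicted_label!r}")
        table[alert.predicted_label] += 1
    table["Total"] = sum(table[l] for l in scheme.positive_labels)
    return table


def reporting_rate_pct(n_reported: int, n_confirmed: int) -> float:
    """Spontaneous-reporting coverage: reported cases as % of confirmed cases."""
    if n_confirmed <= 0:
        raise ValueError("n_confirmed must be positive")
    return round(100.0 * n_reported / n_confirmed, 2)
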