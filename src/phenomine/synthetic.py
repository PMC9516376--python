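"""Seeded generator of synthetic tagged clinical corpora.

Real training corpora for this task are private hospital data, so the
generator emulates their statistical shape instead: long documents (log-normal
unit counts, heavy right tail, default mean ≈ 4000 units with maxima in the
tens of thousands), an imbalanced label distribution (defaults mirror the
drug-hypersensitivity training split: 56/44/18/32 positives against 323
negatives), and a small number of keyword-bearing marker sentences buried in
each positive document.  Background sentences come from a boilerplate bank
screened to contain no keyword, so separability is exact by construction and
noise enters only through two explicit dials: ``keyword_injection_prob``
(chance a positive document receives its marker sentences) and
``leakage_prob`` (chance a fallback document receives a stray marker).

The generated text is template boilerplate, not clinically realistic
language; it exercises the pipeline's arithmetic, not its linguistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus import DHR_SCHEME, SMOKING_SCHEME, Document, LabeledCorpus, LabelScheme
from .keywords import KeywordList, contains_keyword, load_builtin_keywords
from .segmentation import count_units

# Ward-routine boilerplate, screened at generation time against the active
# keyword list (the screen would fail loudly if a term crept in).
_ZH_BOILERPLATE = [
    "患儿今日一般情况可。",
    "体温正常，脉搏每分钟九十次。",
    "双肺呼吸音清，未闻及干湿啰音。",
    "腹软，无压痛及反跳痛。",
    "神志清楚，精神反应可。",
    "心律齐，心音有力，未闻及杂音。",
    "继续目前治疗方案，注意观察病情变化。",
    "血常规检查结果大致正常。",
    "饮食睡眠可，大小便正常。",
    "今日查房，病情平稳。",
    "完善相关检查，必要时复查。",
    "肝脾肋下未触及。",
    "四肢活动自如，肌力正常。",
    "家属对病情表示理解。",
    "尿量正常，出入量平衡。",
    "伤口愈合良好，无渗出。",
    "患儿夜间睡眠安稳。",
    "医嘱已执行，无特殊不适。",
]

_EN_BOILERPLATE = [
    "Patient resting comfortably in bed.",
    "Vital signs stable throughout the shift.",
    "Lungs clear to auscultation bilaterally.",
    "Abdomen soft and nontender.",
    "Continue current medications as ordered.",
    "Labs reviewed and within normal limits.",
    "Diet advanced as tolerated.",
    "Ambulating without assistance.",
    "Follow up with primary care in two weeks.",
    "No acute distress noted on exam.",
    "Heart regular rate and rhythm without murmur.",
    "Incision clean dry and intact.",
    "Pain well controlled with oral analgesics.",
    "Neurologic exam grossly intact.",
    "Discharge planning discussed with family.",
]

# Marker templates: each positive label uses keywords specific to its subtype
# so classes stay distinguishable after embedding.
_DHR_MARKERS: dict[str, list[str]] = {
    "SJS": [
        "皮肤出现多形红斑，口腔黏膜侵蚀明显。",
        "考虑Stevens-Johnson综合征，眼部黏膜受累。",
        "躯干红斑进行性扩大，伴黏膜糜烂。",
    ],
    "DIHS": [
        "用药后全身斑丘疹，伴肝功能异常，诊断药物超敏反应综合征。",
        "迟发性超敏表现，嗜酸性粒细胞升高。",
        "考虑药物超敏反应综合征，停用可疑药物。",
    ],
    "AS": [
        "突发喘鸣及支气管痉挛，血压下降，考虑过敏性休克。",
        "立即予肾上腺素肌注抢救。",
        "输注后数分钟出现过敏性休克表现。",
    ],
    "EB": [
        "躯干见松弛性水疱及表皮剥脱。",
        "考虑大疱表皮松解症，创面予保护性敷料。",
        "尼氏征阳性，表皮松解面积扩大。",
    ],
}

_SMOKING_MARKERS: dict[str, list[str]] = {
    "PAST": [
        "He smoked two packs daily until five years ago.",
        "Former smoker, quit after bypass surgery.",
    ],
    "CURRENT": [
        "She smokes one pack per day at present.",
        "Ongoing smoking despite repeated counseling.",
    ],
    "NON": [
        "Denies any cigarette use.",
        "No history of tobacco exposure reported.",
    ],
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic corpus.

    ``doc_length_mean`` is the mean background length in language units
    (Chinese characters / English tokens); lengths are log-normal with
    log-scale spread ``doc_length_sigma`` and clipped to
    ``[doc_length_min, doc_length_max]``.
    """

    scheme: LabelScheme = DHR_SCHEME
    n_per_label: dict[str, int] = field(
        default_factory=lambda: {"SJS": 56, "DIHS": 44, "AS": 18, "EB": 32, "NEG": 323}
    )
    doc_length_mean: float = 4000.0
    doc_length_sigma: float = 0.7
    doc_length_min: int = 200
    doc_length_max: int = 30000
    keyword_injection_prob: float = 1.0
    leakage_prob: float = 0.0
    marker_vocab: dict[str, list[str]] = field(default_factory=lambda: dict(_DHR_MARKERS))
    language: str = "zh"
    seed: int = 0
    keywords: KeywordList | None = None  # active list; None loads the preset

    def active_keywords(self) -> KeywordList:
        if self.keywords is not None:
            return self.keywords
        return load_builtin_keywords("dhr_guideline" if self.language == "zh" else "smoking")

    def validate(self) -> None:
        for p in (self.keyword_injection_prob, self.leakage_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 0 for n in self.n_per_label.values()):
            raise ValueError("n_per_label counts must be non-negative")
        kw = self.active_keywords()
        for label in self.scheme.positive_labels:
            if self.n_per_label.get(label, 0) == 0:
                continue
            templates = self.marker_vocab.get(label)
            if not templates:
                raise ValueError(f"no marker templates for positive label {label!r}")
            for template in templates:
                if not contains_keyword(template, kw):
                    raise ValueError(
                        f"marker template for {label!r} contains no keyword: {template!r}"
                    )
        bank = _ZH_BOILERPLATE if self.language == "zh" else _EN_BOILERPLATE
        leaking = [s for s in bank if contains_keyword(s, kw)]
        if leaking:
            raise ValueError(f"boilerplate sentences contain keywords: {leaking}")


def smoking_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """English smoking-status corpus shaped like the discharge-summary task."""
    defaults = dict(
        scheme=SMOKING_SCHEME,
        n_per_label={"PAST": 36, "CURRENT": 35, "NON": 66, "UNKNOWN": 252},
        doc_length_mean=766.0,
        doc_length_sigma=0.6,
        doc_length_min=50,
        doc_length_max=4000,
        marker_vocab=dict(_SMOKING_MARKERS),
        language="en",
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _make_text(
    rng: np.random.Generator,
    config: GeneratorConfig,
    label: str,
    bank: list[str],
) -> str:
    target = float(
        np.clip(
            rng.lognormal(
                mean=np.log(config.doc_length_mean) - config.doc_length_sigma**2 / 2,
                sigma=config.doc_length_sigma,
            ),
            config.doc_length_min,
            config.doc_length_max,
        )
    )
    sentences: list[str] = []
    units = 0
    while units < target:
        s = bank[int(rng.integers(len(bank)))]
        sentences.append(s)
        units += count_units(s, config.language)

    is_positive = label != config.scheme.fallback_label
    if is_positive:
        if rng.random() < config.keyword_injection_prob:
            templates = config.marker_vocab[label]
            for _ in range(int(rng.integers(1, 4))):
                marker = templates[int(rng.integers(len(templates)))]
                sentences.insert(int(rng.integers(len(sentences) + 1)), marker)
    elif config.leakage_prob and rng.random() < config.leakage_prob:
        pool = [t for l in config.scheme.positive_labels for t in config.marker_vocab.get(l, [])]
        marker = pool[int(rng.integers(len(pool)))]
        sentences.insert(int(rng.integers(len(sentences) + 1)), marker)

    sep = " " if config.language == "en" else ""
    return sep.join(sentences)


def generate_corpus(config: GeneratorConfig) -> LabeledCorpus:
    """Generate a labeled corpus; byte-identical for a fixed config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bank = _ZH_BOILERPLATE if config.language == "zh" else _EN_BOILERPLATE
    documents: list[Document] = []
    for label in config.scheme.labels:
        for i in range(config.n_per_label.get(label, 0)):
            documents.append(
                Document(
                    doc_id=f"{label}-{i:04d}",
                    text=_make_text(rng, config, label, bank),
                    language=config.language,
                    label=label,
                )
            )
    return LabeledCorpus(documents=documents, scheme=config.scheme)


def generate_archive(
    config: GeneratorConfig, n_docs: int, positive_rate: float
) -> tuple[list[Document], dict[str, str]]:
    """Generate an unlabeled document stream plus a withheld truth table.

    The number of positives is ``round(n_docs * positive_rate)``, spread
    round-robin over the scheme's positive labels; the stream order is
    shuffled.  Returns ``(documents, truth)`` where ``truth`` maps doc_id to
    the hidden gold label (fallback for negatives).
    """
    config.validate()
    if not 0.0 <= positive_rate <= 1.0:
        raise ValueError("positive_rate must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    bank = _ZH_BOILERPLATE if config.language == "zh" else _EN_BOILERPLATE
    n_pos = int(round(n_docs * positive_rate))
    cycle = itertools.cycle(config.scheme.positive_labels)
    hidden = [next(cycle) for _ in range(n_pos)]
    hidden += [config.scheme.fallback_label] * (n_docs - n_pos)
    order = rng.permutation(n_docs)

    documents: list[Document] = []
    truth: dict[str, str] = {}
    for rank, idx in enumerate(order):
        label = hidden[int(idx)]
        doc_id = f"archive-{rank:05d}"
        documents.append(
            Document(
                doc_id=doc_id,
                text=_make_text(rng, config, label, bank),
                language=config.language,
                label=None,
            )
        )
        truth[doc_id] = label
    return documents, truth
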