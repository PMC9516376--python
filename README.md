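# phenomine

Keyword-driven phenotyping of long clinical documents, built for mining rare
adverse-event cases — severe drug hypersensitivity reactions (DHR) in
particular — from archives of free-text electronic health records.

## The problem

A hospital's spontaneous reporting system captures only a fraction of severe
drug hypersensitivity reactions (anaphylactic shock, drug-induced
hypersensitivity syndrome, Stevens-Johnson syndrome, epidermolysis bullosa).
The evidence for the missed cases sits in free-text clinical notes, and one
inpatient visit concatenates to thousands of Chinese characters — far past the
length limit of contextual text encoders. phenomine treats case detection as
long-document classification and attacks the length problem with **key
sentence selection**: keep only the sentences containing task keywords
(hand-picked from the clinical guidelines for each reaction subtype, or
derived by TF-IDF), then embed and classify that short evidence text.

The pipeline is

```
corpus → split sentences → keep keyword sentences → embed → classifier → alerts
```

with every stage a scikit-learn-style estimator:

- `KeySentenceSelector` — transformer from raw text to its keyword-bearing
  sentences (Chinese keywords match by substring, English at word boundaries);
- `HashNgramVectorizer` / `TruncatingEncoderVectorizer` /
  `MeanSentenceVectorizer` — embedding backends: deterministic hashed
  character n-grams (offline, no model download), first-block truncation
  through an external pretrained encoder, or the mean of per-sentence
  encoder vectors (hierarchical representation);
- `GridSearchTextClassifier` — one-vs-rest linear SGD or SVC tuned by
  stratified 10-fold cross-validated grid search, scored by micro-averaged
  F1 = 2·ΣTP / (2·ΣTP + ΣFP + ΣFN) with tallies pooled over classes;
- `PhenotypePipeline` — the persistable bundle applied by `mine_archive` to
  an untagged document stream, emitting alert records with evidence
  sentences for clinician review.

Two diagnostic tools quantify what selection costs: the **oracle test**
(assign each keyword-bearing document its gold tag, everything else the
fallback tag, score micro-F1 — an upper bound on what any classifier can
recover after selection) and length statistics of original versus selected
text. A seeded synthetic-corpus generator (`phenomine.synthetic`) reproduces
the statistical shape of the private study data — log-normal document
lengths, imbalanced classes, a few marker sentences per positive document —
so the whole pipeline is testable without any restricted corpus.

## Worked example

```python
import phenomine as pm

# synthetic corpus shaped like the DHR training split (473 docs, 5 classes)
corpus = pm.generate_corpus(pm.GeneratorConfig(seed=41))
train, test = pm.split_corpus(corpus, 0.2, seed=42)

keywords = pm.load_builtin_keywords("dhr_guideline")
print(len(keywords))                              # 46
print(pm.oracle_test(corpus, keywords))           # 1.0
print(pm.selection_report(corpus, keywords)["original"])  # {'max_units': 30008, 'mean_units': 3984}
print(pm.selection_report(corpus, keywords)["selected"])  # {'max_units': 84, 'mean_units': 12}

pipe = pm.PhenotypePipeline(
    scheme=pm.DHR_SCHEME,
    selector=pm.KeySentenceSelector(keywords="dhr_guideline", language="zh"),
    vectorizer=pm.HashNgramVectorizer(dim=1024),
    classifier=pm.GridSearchTextClassifier(family="sgd_linear", folds=10, seed=43),
).fit(train)
print(pm.micro_f1(test.labels, pipe.predict_corpus(test)))  # 1.0 on held-out docs
```

Selection shrinks a mean document of ~4000 characters to ~12 characters of
evidence while the oracle stays at 1.0 (the generator injects keywords into
every positive), and the classifier recovers the held-out labels exactly;
the same pipeline fitted on original text scores 0.68. The same objects
drive the CLI:

```
phenomine generate --preset dhr --seed 1 --out corpus.jsonl
phenomine oracle   --corpus corpus.jsonl --keywords dhr_guideline
phenomine train    --corpus corpus.jsonl --out model.joblib
phenomine mine     --model model.joblib --input corpus.jsonl \
                   --out alerts.jsonl --summary summary.json
```

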