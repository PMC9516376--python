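# Methods

## Task model

Case detection is single-label multiclass document classification. A
document is all free text generated during one inpatient visit; its label is
one of four severe drug-hypersensitivity subtypes (SJS, DIHS, AS, EB) or NEG,
the no-evidence fallback. The smoking-status scheme (PAST, CURRENT, NON,
UNKNOWN; the ambiguous generic "smoker" class excluded) ships as a second
preset for English discharge-summary-shaped data. Labels are opaque strings
throughout; a `LabelScheme` carries the vocabulary and designates the
fallback.

## Sentence segmentation and length units

Sentences are split on terminal punctuation — `。！？；` and newline for
Chinese, `. ! ? ;` and newline for English — with trailing punctuation kept
attached, so splitting is idempotent on its own output. Semicolons are
boundaries in both languages because clinical notes chain findings with them
and keyword evidence is local to the clause. No abbreviation dictionary or
trained boundary model is used; for keyword selection an over-eager split
only shortens evidence fragments, it cannot lose a keyword.

Length is counted in the unit natural to each script: whitespace-delimited
tokens for English, non-whitespace characters for Chinese. A mixed-script
document uses its declared language's unit. Reported means are rounded
half-up to integers to match table-style presentation; the underlying
functions return floats.

## Keywords and matching

Two lists are built in: the seven smoking unigrams (cigarette, smoke,
smoked, smoker, smokes, smoking, tobacco) and the 46 Chinese guideline terms
for the four DHR subtypes (disease names with their Latin abbreviations,
symptom terms, and treatment drugs). Chinese terms match as contiguous
substrings — Chinese has no word delimiters — while English terms match
whole tokens case-insensitively, so "smoke" does not fire inside
"smokescreen".

TF-IDF keyword derivation mirrors the unsupervised alternative: fit TF-IDF
over training documents (English: whitespace tokens; Chinese: character
unigrams + bigrams, avoiding any segmenter dependency), take the top 2000
candidates by maximum TF-IDF weight, drop terms containing digits,
out-of-script characters or punctuation, then score each survivor by its
mean TF-IDF in positive documents minus its mean in fallback documents and
keep positive scores, ordered descending. The discriminative difference
score is a design choice: a raw TF-IDF threshold of zero would retain every
observed term, so "score" must mean a positive-versus-fallback contrast for
the filter to bind. The exact surviving-term count depends on tokenization
and the TF-IDF variant (we use scikit-learn's smoothed IDF with L2
normalization) and is corpus-bound, not a reproducible constant.

## Key-sentence selection and the oracle

Selection keeps exactly the keyword-bearing sentences, joined in original
order (space-joined for English, directly concatenated for Chinese —
sentences keep their terminal punctuation, so no delimiter information is
lost). Selection is idempotent and monotone in the keyword list. Empty
selections are preserved as empty strings and flow to the embedding stage
rather than short-circuiting to the fallback label: train and inference
paths stay identical and the classifier learns the empty-evidence → fallback
mapping (the hash embedding of an empty string is the zero vector).

The oracle test assigns each keyword-bearing document its gold tag and every
keyword-free document the fallback tag, scoring micro-F1. A fallback
document that mentions a keyword is still scored correct (its gold tag *is*
the fallback), so oracle errors come only from keyword-free positives. This
makes the oracle an upper bound on the selected-text pipeline and a direct
audit of keyword coverage.

## Embedding backends

Three interchangeable transformers produce fixed-dimension document vectors:

- **hash_ngram** (default, offline): character 1–3-gram counts hashed into
  `dim` buckets (scikit-learn HashingVectorizer, fixed hash, unsigned) and
  L2-normalized; empty text maps to the zero vector, everything else to a
  unit vector. Fully deterministic, bit-for-bit reproducible.
- **truncate_encoder**: keep the first `max_tokens` tokens (default 512;
  characters for Chinese, whitespace tokens for English) and encode one
  block with an external pretrained sentence encoder.
- **hierarchy_mean**: encode each sentence separately (each truncated to
  `max_tokens`) and take the unweighted element-wise mean — the
  mean-aggregation flavour of hierarchical document representation; other
  aggregators are out of scope.

External encoders are resolved from an id-string registry
(`register_encoder` / `resolve_encoder`). The package never bundles or
re-implements a pretrained encoder; an unknown id raises
`EncoderUnavailableError` rather than silently substituting, and the
built-in `hash-ngram` encoder is the registry's only default entry, which
also serves as the deterministic sentence encoder in tests of the truncation
and hierarchy code paths. Pooling inside an external encoder is that
encoder's own; the id string is recorded for provenance.

## Classification and evaluation

Micro-averaged F1 pools TP/FP/FN over classes: 2·ΣTP / (2·ΣTP + ΣFP + ΣFN).
For single-label multiclass predictions each error is one FP and one FN
simultaneously, so micro-F1 equals accuracy; the implementation still
derives it from the pooled tallies so evaluation reports carry per-class
counts and the confusion matrix. Tests cross-check against an independent
brute-force tally and scikit-learn's metric.

Classifiers are one-vs-rest wrappers (the common default for both learner
families; the choice matters little at these scales) around linear SGD or
SVC, tuned by grid search under stratified k-fold CV (default 10 folds,
shuffled with a fixed seed; folds are reduced with a warning when the
smallest class is smaller than the fold count, which real test splits with
3-member classes require). Default grids — SGD: loss {hinge, log_loss} ×
alpha {1e-5 … 1e-1 log-spaced}; SVC: C {0.1, 1, 10, 100} × kernel {linear,
rbf} — are ordinary small grids, recorded in the fitted model for
provenance. Ties are broken by grid order; everything is deterministic for
a fixed seed.

## Archive mining

`mine_archive` runs select → embed → predict per document in a single pass
(constant memory per document, output invariant to stream chunking) and
emits an `AlertRecord` only for positive-class predictions, carrying the
evidence sentences and selected length. Expert confirmation of alerts is a
human step outside the package; the summary table reports per-subtype alert
counts with a total row that always equals the column sum, and
`reporting_rate_pct` expresses spontaneous-reporting coverage as reported /
confirmed × 100, rounded to two decimals. Malformed (empty-text) stream
records are skipped with a warning in lenient mode and raise in strict mode.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes,
because the real corpora (private hospital DHR data; data-use-restricted
smoking summaries) cannot ship:

- **class balance**: defaults are the DHR training-split counts
  SJS 56 / DIHS 44 / AS 18 / EB 32 / NEG 323 (≈2:1 negative:positive);
  a smoking preset mirrors 36/35/66/252.
- **document length**: log-normal in language units (heavy-tailed, like
  clinical note lengths), default mean 4000 with log-sd 0.7, clipped to
  [200, 30000], giving maxima in the mid-20000s over ~500 documents —
  matching the scale of the real corpus statistics. The smoking preset uses
  mean 766 tokens.
- **evidence structure**: background sentences are drawn from a boilerplate
  bank screened at generation time to contain no active keyword; each
  positive document receives 1–3 label-specific marker sentences (with
  probability `keyword_injection_prob`, default 1.0) whose keywords are
  disjoint across labels, and fallback documents receive a stray marker
  with probability `leakage_prob` (default 0.0). Separability is therefore
  exact by construction and noise enters only through these two dials.

Everything is reproducible from the config seed. What passing tests show:
the pipeline's arithmetic, determinism, and parameter recovery under the
stated noise model. What they do not show: robustness to real clinical
language — synonymy, negation, misspelling, keyword mentions in
family/negative contexts — or to patient-level longitudinal structure, none
of which the template text models.

## Problem sizes and numerical choices

The acceptance script and the heavier tests run the full default corpus
(473 documents, mean 4000 characters) for oracle, reduction and
parameter-recovery checks; the partial-injection oracle check uses 1000
positives at mean length 800 (oracle arithmetic is length-invariant, and
the binomial 99% interval on keyword-free positives needs the positive
count, not the length). Stratified splitting apportions per-class test
counts by largest remainder; the derived-seed chain in the acceptance
script offsets the base seed per stage. Ties in TF-IDF ranking are broken
by candidate order (stable sort). Degenerate inputs fail loudly: empty
corpora for length stats, single-class training data, sub-2-member classes
for stratification, dimension mismatches at prediction.

## Known limitations

Keyword lists are surface forms: no synonym expansion, stemming, or
terminology-ontology mapping. Sentence splitting is purely punctuation
based. The oracle upper-bounds selection loss but says nothing about
embedding or classifier loss. Published benchmark scores on the restricted
corpora are not reproducible here and are not targeted; directional claims
(selection reduces length; selected-text pipelines score at least as well
as original-text pipelines on keyword-separable data) are verified on
synthetic corpora only.
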