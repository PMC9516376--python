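import numpy as np
import pytest

from phenomine import (
    EmbedderConfig,
    EncoderUnavailableError,
    HashNgramVectorizer,
    MeanSentenceVectorizer,
    TruncatingEncoderVectorizer,
    load_builtin_keywords,
    make_vectorizer,
    select_key_sentences,
)
from phenomine.embedding import embed_hash_ngram, resolve_encoder


class TestHashNgram:
    def test_identical_texts_identical_vectors(self):
        vec = HashNgramVectorizer(dim=256).fit([])
        a, b = vec.transform(["患儿出现红斑。", "患儿出现红斑。"])
        assert np.array_equal(a, b)

    def test_nonempty_text_has_unit_norm(self):
        vec = HashNgramVectorizer(dim=256).fit([])
        out = vec.transform(["hello world", "红斑"])
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_empty_text_is_zero_vector(self):
        vec = HashNgramVectorizer(dim=64).fit([])
        assert np.array_equal(vec.transform([""])[0], np.zeros(64))

    def test_dimension_constant_across_documents(self):
        vec = HashNgramVectorizer(dim=128).fit([])
        out = vec.transform(["a", "bb", "ccc", ""])
        assert out.shape == (4, 128)

    def test_bitwise_run_to_run_determinism(self):
        a = HashNgramVectorizer(dim=512).fit([]).transform(["some clinical text."])
        b = HashNgramVectorizer(dim=512).fit([]).transform(["some clinical text."])
        assert a.tobytes() == b.tobytes()

    def test_functional_wrapper(self):
        config = EmbedderConfig(backend="hash_ngram", dim=128)
        dv = embed_hash_ngram("text", config, doc_id="d1")
        assert dv.doc_id == "d1" and dv.values.shape == (128,)

    def test_separability_nearest_centroid(self, small_dhr_corpus):
        """Classes with disjoint marker vocabularies separate in hash space."""
        keywords = load_builtin_keywords("dhr_guideline")
        positives = [d for d in small_dhr_corpus if d.label != "NEG"]
        texts = [select_key_sentences(d, keywords).selected_text for d in positives]
        labels = np.array([d.label for d in positives])
        X = HashNgramVectorizer(dim=1024).fit([]).transform(texts)
        centroids = {l: X[labels == l].mean(axis=0) for l in set(labels)}
        correct = 0
        for row, gold in zip(X, labels):
            pred = min(centroids, key=lambda l: np.linalg.norm(row - centroids[l]))
            correct += pred == gold
        assert correct / len(labels) >= 0.95


class TestEncoderBackends:
    def test_unknown_encoder_id_raises_explicitly(self):
        with pytest.raises(EncoderUnavailableError):
            resolve_encoder("bert-base-uncased")
        with pytest.raises(EncoderUnavailableError):
            TruncatingEncoderVectorizer(encoder_id="clinical-bert").fit([])

    def test_truncation_discards_tail_difference(self):
        vec = TruncatingEncoderVectorizer(
            encoder_id="hash-ngram", max_tokens=5, language="en", dim=128
        ).fit([])
        shared = "one two three four five"
        a, b = vec.transform([shared + " six", shared + " seven eight"])
        assert np.array_equal(a, b)

    def test_truncation_zh_counts_characters(self):
        vec = TruncatingEncoderVectorizer(
            encoder_id="hash-ngram", max_tokens=4, language="zh", dim=128
        ).fit([])
        a, b = vec.transform(["患儿发热不退。", "患儿发热好转。"])
        assert np.array_equal(a, b)

    def test_empty_text_is_finite(self):
        vec = TruncatingEncoderVectorizer(encoder_id="hash-ngram", dim=64).fit([])
        assert np.all(np.isfinite(vec.transform([""])))

    def test_registry_colon_syntax_sets_dim(self):
        assert resolve_encoder("hash-ngram:32").dim == 32


class TestHierarchyMean:
    def test_single_sentence_equals_its_own_embedding(self):
        hier = MeanSentenceVectorizer(encoder_id="hash-ngram", language="en", dim=128).fit([])
        flat = TruncatingEncoderVectorizer(
            encoder_id="hash-ngram", max_tokens=512, language="en", dim=128
        ).fit([])
        text = "Patient resting comfortably."
        assert np.allclose(hier.transform([text])[0], flat.transform([text])[0])

    def test_repeated_sentence_mean_invariance(self):
        hier = MeanSentenceVectorizer(encoder_id="hash-ngram", language="en", dim=128).fit([])
        one = hier.transform(["Stable overnight."])[0]
        three = hier.transform(["Stable overnight. Stable overnight. Stable overnight."])[0]
        assert np.allclose(one, three)

    def test_empty_text_gives_zero_vector(self):
        hier = MeanSentenceVectorizer(encoder_id="hash-ngram", language="en", dim=64).fit([])
        assert np.array_equal(hier.transform([""])[0], np.zeros(64))

    def test_mean_of_opposite_vectors_is_zero(self):
        class PlusMinus:
            dim = 2

            def encode(self, texts):
                return np.array(
                    [[1.0, 0.0] if t.startswith("p") else [-1.0, 0.0] for t in texts]
                )

        from phenomine.embedding import register_encoder

        register_encoder("plusminus", PlusMinus)
        hier = MeanSentenceVectorizer(encoder_id="plusminus", language="en").fit([])
        out = hier.transform(["plus one. minus one."])[0]
        assert np.allclose(out, np.zeros(2))


class TestMakeVectorizer:
    @pytest.mark.parametrize(
        "backend, cls",
        [
            ("hash_ngram", HashNgramVectorizer),
            ("truncate_encoder", TruncatingEncoderVectorizer),
            ("hierarchy_mean", MeanSentenceVectorizer),
        ],
    )
    def test_backend_dispatch(self, backend, cls):
        config = EmbedderConfig(backend=backend, encoder_id="hash-ngram", dim=64)
        assert isinstance(make_vectorizer(config), cls)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EmbedderConfig(backend="bogus")
        with pytest.raises(ValueError):
            EmbedderConfig(max_tokens=0)
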