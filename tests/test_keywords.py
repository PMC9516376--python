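import pytest

from phenomine import (
    DHR_SCHEME,
    Document,
    LabeledCorpus,
    KeywordList,
    contains_keyword,
    extract_tfidf_keywords,
    load_builtin_keywords,
)


class TestBuiltinLists:
    def test_smoking_list_is_the_seven_unigrams(self):
        kw = load_builtin_keywords("smoking")
        assert kw.terms == (
            "cigarette", "smoke", "smoked", "smoker", "smokes", "smoking", "tobacco",
        )
        assert kw.provenance == "builtin_smoking"
        assert kw.match_mode == "word_boundary"

    def test_guideline_list_contains_published_terms(self):
        kw = load_builtin_keywords("dhr_guideline")
        assert kw.provenance == "builtin_guideline"
        assert kw.match_mode == "substring"
        for term in ("Stevens-Johnson综合征", "肾上腺素", "AS", "EB", "TEN", "SJS",
                     "DIHS", "过敏性休克", "大疱表皮松解症", "红斑", "IVIG"):
            assert term in kw.terms
        assert len(set(kw.terms)) == len(kw.terms)

    def test_loading_twice_is_identical(self):
        assert load_builtin_keywords("dhr_guideline") == load_builtin_keywords("dhr_guideline")

    def test_unknown_task(self):
        with pytest.raises(ValueError):
            load_builtin_keywords("asthma")


class TestKeywordList:
    def test_from_terms_dedupes_preserving_order(self):
        kw = KeywordList.from_terms(["b", "a", "b", " a "], "tfidf_derived", "substring")
        assert kw.terms == ("b", "a")

    def test_round_trip_file(self, tmp_path):
        kw = KeywordList.from_terms(["红斑", "过敏"], "tfidf_derived", "substring")
        path = tmp_path / "kw.txt"
        kw.save(path)
        assert KeywordList.load(path).terms == kw.terms

    def test_rejects_duplicates_and_empties(self):
        with pytest.raises(ValueError):
            KeywordList(terms=("a", "a"), provenance="tfidf_derived", match_mode="substring")
        with pytest.raises(ValueError):
            KeywordList(terms=("a", ""), provenance="tfidf_derived", match_mode="substring")


class TestContainsKeyword:
    @pytest.mark.parametrize(
        "sentence, expected",
        [
            ("患儿出现红斑。", True),           # substring hit
            ("予肾上腺素抢救。", True),
            ("今日查房，病情平稳。", False),
        ],
    )
    def test_substring_mode_chinese(self, sentence, expected):
        kw = load_builtin_keywords("dhr_guideline")
        assert contains_keyword(sentence, kw) is expected

    @pytest.mark.parametrize(
        "sentence, expected",
        [
            ("He smokes daily.", True),
            ("SMOKING history positive.", True),   # case-insensitive
            ("No relevant history.", False),
            ("Deployed a smokescreen yesterday.", False),  # no hit inside a token
            ("", False),
        ],
    )
    def test_word_boundary_mode_english(self, sentence, expected):
        kw = load_builtin_keywords("smoking")
        assert contains_keyword(sentence, kw) is expected

    def test_matching_is_total_and_deterministic(self):
        kw = load_builtin_keywords("smoking")
        sentences = ["He smokes.", "", "plain text", "tobacco-free ward"]
        first = [contains_keyword(s, kw) for s in sentences]
        assert first == [contains_keyword(s, kw) for s in sentences]
        assert all(isinstance(v, bool) for v in first)


def _tiny_corpus(texts_labels, language="en"):
    docs = [
        Document(doc_id=f"d{i}", text=t, language=language, label=l)
        for i, (t, l) in enumerate(texts_labels)
    ]
    scheme = DHR_SCHEME
    return LabeledCorpus(documents=docs, scheme=scheme)


class TestExtractTfidfKeywords:
    def test_marker_term_in_all_positives_retained_with_top_score(self):
        corpus = _tiny_corpus(
            [
                ("severe rash noted today", "SJS"),
                ("rash spreading on trunk", "SJS"),
                ("routine vitals recorded today", "NEG"),
                ("stable overnight no events", "NEG"),
            ]
        )
        kw = extract_tfidf_keywords(corpus, top_n=50)
        assert kw.terms[0] == "rash"
        assert kw.provenance == "tfidf_derived"

    def test_terms_with_digits_or_punctuation_removed(self):
        corpus = _tiny_corpus(
            [
                ("covid19 rash x-ray positive", "SJS"),
                ("covid19 rash seen again", "SJS"),
                ("routine checkup done", "NEG"),
                ("nothing acute found", "NEG"),
            ]
        )
        kw = extract_tfidf_keywords(corpus, top_n=50)
        assert "covid19" not in kw.terms
        assert "x-ray" not in kw.terms
        assert "rash" in kw.terms

    def test_zh_candidates_are_cjk_unigrams_and_bigrams(self):
        corpus = _tiny_corpus(
            [
                ("患儿红斑明显。", "SJS"),
                ("红斑加重。", "SJS"),
                ("病情平稳。", "NEG"),
                ("今日无特殊。", "NEG"),
            ],
            language="zh",
        )
        kw = extract_tfidf_keywords(corpus, top_n=100)
        assert "红斑" in kw.terms
        assert all(len(t) <= 2 for t in kw.terms)
        assert kw.match_mode == "substring"

    def test_output_bounded_by_top_n(self, small_dhr_corpus):
        kw = extract_tfidf_keywords(small_dhr_corpus, top_n=30)
        assert 0 < len(kw.terms) <= 30

    def test_negative_only_terms_dropped(self):
        corpus = _tiny_corpus(
            [
                ("rash noted", "SJS"),
                ("rash again", "SJS"),
                ("ventilator weaning continues", "NEG"),
                ("ventilator settings unchanged", "NEG"),
            ]
        )
        kw = extract_tfidf_keywords(corpus, top_n=50)
        assert "ventilator" not in kw.terms

    def test_single_class_corpus_errors(self):
        corpus = _tiny_corpus([("rash", "SJS"), ("rash two", "SJS")])
        with pytest.raises(ValueError):
            extract_tfidf_keywords(corpus)
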