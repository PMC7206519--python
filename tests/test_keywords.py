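import math

import pytest
from hypothesis import given, settings, strategies as st

from edurec.corpus import build_corpus
from edurec.keywords import (ALL_STRATEGIES, KeywordSet, StrategyConfig,
                             candidate_filter, character_cosine,
                             eliminate_synonyms, extract_keywords,
                             textrank_scores, tfidf_scores)

from conftest import textrank_oracle

WEIGHTS_ON = StrategyConfig(strategies=frozenset({"weights"}))


class TestCandidateFilter:
    def test_stopwords_and_short_surfaces_removed(self):
        corpus = build_corpus([("d", "", "高血压 的 治疗 x", True)])
        out = candidate_filter(corpus.get("d"), stopwords=frozenset({"的"}))
        assert [t.surface for t in out] == ["高血压", "治疗"]

    def test_all_stopwords_gives_empty(self):
        corpus = build_corpus([("d", "", "aa bb", True)])
        assert candidate_filter(corpus.get("d"), frozenset({"aa", "bb"})) == []

    def test_no_stopwords_keeps_all_multichar(self):
        corpus = build_corpus([("d", "", "aa bb cc", True)])
        assert len(candidate_filter(corpus.get("d"))) == 3


class TestTfidf:
    def test_hand_computed_scores_weights_off(self, tiny_corpus):
        scores = tfidf_scores(tiny_corpus, tiny_corpus.get("D1"))
        assert scores["xx"] == pytest.approx(2 * (math.log(3 / 2) + 1))
        assert scores["yy"] == pytest.approx(1.0)
        assert max(scores, key=scores.get) == "xx"

    def test_title_and_pos_weights_flip_ranking(self, titled_corpus):
        off = tfidf_scores(titled_corpus, titled_corpus.get("D1"))
        assert max(off, key=off.get) == "xx"
        on = tfidf_scores(titled_corpus, titled_corpus.get("D1"), WEIGHTS_ON)
        # yy: tf 1 * idf 1 * title 3 * noun 1.2; xx: tf 2 * idf (ln(3/2)+1) * verb 0.8
        assert on["yy"] == pytest.approx(3.6)
        assert on["xx"] == pytest.approx(2 * (math.log(3 / 2) + 1) * 0.8)
        assert on["yy"] > on["xx"]

    def test_single_document_corpus_idf_collapses(self):
        corpus = build_corpus([("d", "", "aa aa bb", True)])
        scores = tfidf_scores(corpus, corpus.get("d"))
        assert scores == {"aa": pytest.approx(2.0), "bb": pytest.approx(1.0)}

    def test_document_not_in_corpus_rejected(self, tiny_corpus):
        foreign = build_corpus([("other", "", "qq", True)]).get("other")
        with pytest.raises(ValueError, match="other"):
            tfidf_scores(tiny_corpus, foreign)

    def test_ranking_invariant_under_uniform_weight_scaling(self):
        # all candidates non-title nouns: every weight scales identically
        corpus = build_corpus([("d", "", "aa/n aa/n bb/n cc/n cc/n cc/n", True)])
        doc = corpus.get("d")
        rank = lambda cfg: sorted(tfidf_scores(corpus, doc, cfg),
                                  key=lambda s: -tfidf_scores(corpus, doc, cfg)[s])
        base = StrategyConfig(weight_noun=1.2, strategies=frozenset({"weights"}))
        scaled = StrategyConfig(weight_noun=6.0, weight_title=15.0, weight_verb=4.0,
                                strategies=frozenset({"weights"}))
        assert rank(base) == rank(scaled)

    def test_weights_never_change_other_pos_non_title_token(self, tiny_corpus):
        doc = tiny_corpus.get("D1")  # untagged tokens are 'other', no title
        assert tfidf_scores(tiny_corpus, doc) == tfidf_scores(tiny_corpus, doc, WEIGHTS_ON)


class TestTextrank:
    def test_two_symmetric_candidates_score_one(self):
        corpus = build_corpus([("d", "", "aa bb", True)])
        scores = textrank_scores(corpus.get("d"))
        assert scores["aa"] == pytest.approx(1.0, abs=1e-5)
        assert scores["bb"] == pytest.approx(1.0, abs=1e-5)

    def test_path_graph_center_dominates(self):
        corpus = build_corpus([("d", "", "aa bb cc", True)])
        scores = textrank_scores(corpus.get("d"), tol=1e-10, max_iter=1000)
        oracle = textrank_oracle(["aa", "bb", "cc"])
        for s in scores:
            assert scores[s] == pytest.approx(oracle[s], abs=1e-8)
        assert scores["bb"] > scores["aa"] == pytest.approx(scores["cc"])

    def test_isolated_candidate_scores_one_minus_damping(self):
        corpus = build_corpus([("d", "", "aa", True)])
        assert textrank_scores(corpus.get("d"))["aa"] == pytest.approx(0.15)

    def test_empty_candidate_list_gives_empty_map(self):
        corpus = build_corpus([("d", "", "a b", True)])  # all single-char
        assert textrank_scores(corpus.get("d")) == {}

    def test_nonconvergence_warns(self):
        corpus = build_corpus([("d", "", "aa bb cc", True)])
        with pytest.warns(RuntimeWarning, match="converge"):
            textrank_scores(corpus.get("d"), max_iter=1)


class TestEliminateSynonyms:
    def test_longer_synonym_retained(self):
        out = eliminate_synonyms([("高血压", 3.0), ("高血压病", 2.0)], 0.5)
        assert out == [("高血压病", 2.0)]
        assert character_cosine("高血压", "高血压病") == pytest.approx(3 / math.sqrt(12))

    def test_disjoint_surfaces_unchanged(self):
        ranked = [("abc", 2.0), ("def", 1.0)]
        assert eliminate_synonyms(ranked, 0.5) == ranked

    def test_length_tie_keeps_higher_scored(self):
        out = eliminate_synonyms([("abc", 2.0), ("acb", 1.0)], 0.5)
        assert out == [("abc", 2.0)]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            eliminate_synonyms([("aa", 1.0)], 1.5)

    @given(st.lists(st.tuples(st.text("abcdef", min_size=2, max_size=5),
                              st.floats(0, 10, allow_nan=False)),
                    min_size=0, max_size=8, unique_by=lambda t: t[0]))
    @settings(derandomize=True, max_examples=100)
    def test_output_subsequence_and_pairwise_below_threshold(self, ranked):
        ranked = sorted(ranked, key=lambda t: -t[1])
        out = eliminate_synonyms(ranked, 0.8)
        it = iter(ranked)
        assert all(item in it for item in out)  # subsequence
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert character_cosine(out[i][0], out[j][0]) < 0.8


class TestExtractKeywords:
    def test_fewer_candidates_than_k_returns_all(self):
        corpus = build_corpus([("d", "", "aa bb cc", True)])
        ks = extract_keywords(corpus, corpus.get("d"), k=5)
        assert len(ks) == 3

    def test_synonym_elimination_promotes_lower_ranks(self):
        # six candidates by descending tf; 'aab' is a synonym of 'aabc'
        body = "aabc aabc aabc aabc aab aab aab xyde xyde qrst"
        corpus = build_corpus([("d", "", body, True)])
        cfg = StrategyConfig(strategies=frozenset({"synonyms"}))
        ks = extract_keywords(corpus, corpus.get("d"), k=3, config=cfg)
        assert "aab" not in ks.surfaces
        assert ks.surfaces[0] == "aabc"
        assert len(ks) == 3

    def test_all_strategies_disabled_equals_baseline(self, titled_corpus):
        doc = titled_corpus.get("D1")
        plain = extract_keywords(titled_corpus, doc, config=StrategyConfig())
        scores = tfidf_scores(titled_corpus, doc)
        expected = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        assert plain.keywords == expected

    def test_unknown_method_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="method"):
            extract_keywords(tiny_corpus, tiny_corpus.get("D1"), method="lda")

    def test_keywordset_invariants_enforced(self):
        with pytest.raises(ValueError):
            KeywordSet("d", [("aa", 1.0), ("aa", 0.5)])
        with pytest.raises(ValueError):
            KeywordSet("d", [("aa", 1.0), ("bb", 2.0)])
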