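import itertools

import numpy as np
import pytest

from edurec.corpus import build_corpus
from edurec.embedding import (EmbeddingTable, MappingParams, TextVector,
                              build_text_vector, cosine, train_embeddings)
from edurec.fixtures import TopicModelSpec, generate_corpus
from edurec.keywords import KeywordSet
from edurec.vectorspace import VectorSpace


def _table_from_rows(rows: dict[str, list[float]]) -> EmbeddingTable:
    dim = len(next(iter(rows.values())))
    return EmbeddingTable(dim, {k: np.array(v, dtype=float) for k, v in rows.items()})


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -2.0, 1.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert cosine(np.zeros(2), np.array([1.0, 0.0])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.ones(2), np.ones(3))


class TestTraining:
    def test_dimension_contract(self, tiny_corpus):
        table = train_embeddings(tiny_corpus, dim=16, epochs=1, seed=0)
        assert all(v.shape == (16,) for v in table.vectors.values())

    def test_min_count_drops_hapax(self):
        corpus = build_corpus([("d", "", "aa aa bb aa hapax aa", True)])
        table = train_embeddings(corpus, dim=8, epochs=1, min_count=2, seed=0)
        assert "hapax" not in table
        assert "aa" in table

    def test_empty_vocabulary_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            train_embeddings(tiny_corpus, dim=8, min_count=99)

    def test_deterministic_for_fixed_seed(self, tiny_corpus):
        t1 = train_embeddings(tiny_corpus, dim=8, epochs=2, seed=7)
        t2 = train_embeddings(tiny_corpus, dim=8, epochs=2, seed=7)
        for s in t1.vectors:
            np.testing.assert_array_equal(t1[s], t2[s])

    def test_same_topic_words_closer_than_cross_topic(self):
        corpus, topics, _ = generate_corpus(TopicModelSpec(seed=11))
        table = train_embeddings(corpus, dim=50, epochs=20, seed=11)
        by_topic = {}
        for doc in corpus:
            term = topics[doc.doc_id]
            by_topic.setdefault(term, set()).update(
                t.surface for t in doc.title_tokens if t.pos == "noun")
        groups = [sorted(v & set(table.vectors)) for v in by_topic.values()]
        same = [cosine(table[a], table[b]) for g in groups
                for a, b in itertools.combinations(g, 2)]
        cross = [cosine(table[a], table[b])
                 for g1, g2 in itertools.combinations(groups, 2)
                 for a in g1 for b in g2]
        assert np.mean(same) > np.mean(cross)


class TestTextVectorFormat:
    def test_word2vec_text_roundtrip(self, tmp_path, tiny_corpus):
        table = train_embeddings(tiny_corpus, dim=8, epochs=1, seed=1)
        path = tmp_path / "emb.txt"
        table.save_text(path)
        loaded = EmbeddingTable.load_text(path)
        assert set(loaded.vectors) == set(table.vectors)
        for s in table.vectors:
            np.testing.assert_allclose(loaded[s], table[s], rtol=1e-4)


class TestBuildTextVector:
    space = VectorSpace(("term1", "term2"))

    def test_keyword_identical_to_term_contributes_one(self):
        table = _table_from_rows({"term1": [1, 0], "term2": [0, 1]})
        tv = build_text_vector(KeywordSet("d", [("term1", 1.0)]), table, self.space)
        np.testing.assert_allclose(tv.values, [1.0, 0.0])

    def test_hand_summed_cosines(self):
        # kw1/kw2 have cosines 0.6 and 0.8 to term1, both below 0.5 to term2
        table = _table_from_rows({
            "term1": [1.0, 0.0],
            "term2": [-1.0, 0.0],
            "kw1": [0.6, 0.8],
            "kw2": [0.8, 0.6],
        })
        ks = KeywordSet("d", [("kw1", 2.0), ("kw2", 1.0)])
        tv = build_text_vector(ks, table, self.space)
        np.testing.assert_allclose(tv.values, [1.4, 0.0], atol=1e-12)

    def test_all_below_threshold_gives_zero_vector(self):
        table = _table_from_rows({"term1": [1, 0], "term2": [0, 1], "kw": [-1, 0]})
        tv = build_text_vector(KeywordSet("d", [("kw", 1.0)]), table, self.space)
        np.testing.assert_array_equal(tv.values, [0.0, 0.0])

    def test_empty_keywords_give_zero_vector(self):
        table = _table_from_rows({"term1": [1, 0], "term2": [0, 1]})
        tv = build_text_vector(KeywordSet("d", []), table, self.space)
        np.testing.assert_array_equal(tv.values, [0.0, 0.0])

    def test_oov_keyword_and_term_contribute_zero(self):
        table = _table_from_rows({"term1": [1.0, 0.0], "kw": [1.0, 0.0]})
        ks = KeywordSet("d", [("kw", 1.0), ("missing", 0.5)])
        tv = build_text_vector(ks, table, self.space)
        np.testing.assert_allclose(tv.values, [1.0, 0.0])

    def test_threshold_one_with_identical_keywords_gives_indicator(self):
        table = _table_from_rows({"term1": [1, 0], "term2": [0, 1], "kw": [0.9, 0.1]})
        ks = KeywordSet("d", [("term1", 2.0), ("kw", 1.0)])
        tv = build_text_vector(ks, table, self.space, MappingParams(threshold=1.0))
        np.testing.assert_allclose(tv.values, [1.0, 0.0])

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            MappingParams(threshold=1.2)

    def _random_case(self, rng, n_terms=5, n_kw=4, dim=6):
        space = VectorSpace(tuple(f"t{i}" for i in range(n_terms)))
        rows = {t: rng.normal(size=dim) for t in space.terms}
        kws = [f"k{i}" for i in range(n_kw)]
        rows.update({k: rng.normal(size=dim) for k in kws})
        table = _table_from_rows({k: list(v) for k, v in rows.items()})
        ks = KeywordSet("d", [(k, float(n_kw - i)) for i, k in enumerate(kws)])
        return space, table, ks

    def test_agrees_with_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            space, table, ks = self._random_case(rng)
            tv = build_text_vector(ks, table, space)
            for j, term in enumerate(space.terms):
                expected = 0.0
                for kw in ks.surfaces:
                    sim = cosine(table[kw], table[term])
                    if sim >= 0.5:
                        expected += sim
                assert tv.values[j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_keywords_and_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            space, table, ks = self._random_case(rng)
            base = build_text_vector(ks, table, space, MappingParams(0.5))
            # appending a keyword never decreases any entry
            extra = KeywordSet("d", ks.keywords + [("k0b", 0.1)])
            table.vectors["k0b"] = rng.normal(size=table.dim)
            grown = build_text_vector(extra, table, space, MappingParams(0.5))
            assert np.all(grown.values >= base.values - 1e-12)
            # raising the threshold never increases any entry
            higher = build_text_vector(ks, table, space, MappingParams(0.7))
            assert np.all(higher.values <= base.values + 1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            TextVector("d", np.array([-0.1, 0.2]))
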