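import math

import numpy as np
import pytest

from opirisk.features import (
    CharEmbeddingTable,
    EmbeddingTable,
    FeatureAssembler,
    FeatureCombination,
    TfidfModel,
    char_embed,
    load_pretrained,
    train_word_embeddings,
)
from opirisk.preprocessing import TokenizedDocument


def _doc(pid, text):
    return TokenizedDocument(pid, text.split())


class TestTfidf:
    def test_shared_term_is_downweighted(self):
        model = TfidfModel(dim=4).fit([_doc("a", "a b"), _doc("b", "a c")])
        idf = dict(zip(model.ngrams_, model.idf_))
        assert idf["a"] < idf["b"]

    def test_default_dimension_is_100(self, sw_control_docs):
        docs, _ = sw_control_docs
        model = TfidfModel().fit(docs[:50])
        X = model.transform(docs[:10])
        assert X.shape == (10, 100)

    def test_values_match_hand_computed_oracle(self):
        """Smoothed idf with raw counts and L2 norm, checked against a
        from-scratch computation on a 3-document corpus."""
        texts = ["the cat sat", "the dog sat here", "a cat and a dog"]
        docs = [_doc(f"d{i}", t) for i, t in enumerate(texts)]
        model = TfidfModel(dim=8).fit(docs)
        X = model.transform(docs)
        # independent oracle
        N = 3
        token_docs = [t.split() for t in texts]
        grams = [toks + [f"{x} {y}" for x, y in zip(toks, toks[1:])]
                 for toks in token_docs]
        counts = {}
        for g in grams:
            for ng in g:
                counts[ng] = counts.get(ng, 0) + 1
        selected = sorted(counts, key=lambda g: (-counts[g], g))[:8]
        assert selected == model.ngrams_
        df = {ng: sum(ng in g for g in grams) for ng in selected}
        expect = np.zeros((3, 8))
        for i, g in enumerate(grams):
            for j, ng in enumerate(selected):
                tf = g.count(ng)
                expect[i, j] = tf * (math.log((1 + N) / (1 + df[ng])) + 1)
            norm = np.linalg.norm(expect[i])
            if norm:
                expect[i] /= norm
        assert np.allclose(X, expect, atol=1e-9)

    def test_document_without_selected_ngrams_is_zero_vector(self):
        model = TfidfModel(dim=4).fit([_doc("a", "a b a b")])
        X = model.transform([_doc("q", "z z z")])
        assert (X == 0).all()

    def test_requesting_more_features_than_ngrams_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="n-grams"):
            model = TfidfModel(dim=100).fit([_doc("a", "a b")])
        assert len(model.ngrams_) == 3  # a, b, "a b"

    def test_json_roundtrip(self, tmp_path):
        model = TfidfModel(dim=6).fit([_doc("a", "x y x"), _doc("b", "y z")])
        model.save(tmp_path / "tfidf.json")
        back = TfidfModel.load(tmp_path / "tfidf.json")
        docs = [_doc("q", "x y z w")]
        assert np.allclose(model.transform(docs), back.transform(docs))


class TestWordEmbeddings:
    def test_identical_contexts_beat_unrelated_pairs(self):
        # "alpha" and "beta" always share contexts; "omega" never does
        docs = []
        for i in range(60):
            docs.append(_doc(f"a{i}", "ctx1 alpha ctx2 ctx3"))
            docs.append(_doc(f"b{i}", "ctx1 beta ctx2 ctx3"))
            docs.append(_doc(f"c{i}", "far omega away distant"))
        table = train_word_embeddings(docs, dim=16, window=2, epochs=8, seed=2)

        def cos(a, b):
            va, vb = table.get(a), table.get(b)
            return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

        assert cos("alpha", "beta") > cos("alpha", "omega")

    def test_dimension_and_determinism(self):
        docs = [_doc("a", "one two three four five six")] * 5
        t1 = train_word_embeddings(docs, dim=12, window=2, epochs=2, seed=9)
        t2 = train_word_embeddings(docs, dim=12, window=2, epochs=2, seed=9)
        assert all(v.shape == (12,) for v in t1.vectors.values())
        for tok in t1.vectors:
            assert np.array_equal(t1.vectors[tok], t2.vectors[tok])

    def test_corpus_smaller_than_window_raises(self):
        with pytest.raises(ValueError):
            train_word_embeddings([_doc("a", "x")], window=5)


class TestPretrained:
    def test_load_and_roundtrip(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("cat 1 0 0 0 0\ndog 0 1 0 0 0\nfish 0 0 1 0 0\n")
        table = load_pretrained(path, seed=1)
        assert table.dim == 5 and len(table.vectors) == 3
        assert table.pretrained
        out = tmp_path / "back.txt"
        table.save(out)
        again = load_pretrained(out, seed=1)
        for tok in table.vectors:
            assert np.allclose(table.vectors[tok], again.vectors[tok], atol=1e-6)

    def test_duplicate_token_rejected(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("cat 1 0\ncat 0 1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_pretrained(path)

    def test_inconsistent_dimension_names_line(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("cat 1 0\ndog 0 1 2\n")
        with pytest.raises(ValueError, match="line 2"):
            load_pretrained(path)

    def test_oov_tokens_share_one_fixed_vector(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("cat 1 0\n")
        table = load_pretrained(path, seed=3)
        assert np.array_equal(table.get("zzz"), table.get("qqq"))
        assert not np.array_equal(table.get("zzz"), np.zeros(2))


class TestCharEmbedding:
    def test_single_character_token_is_its_vector(self):
        table = CharEmbeddingTable.random(dim=8, seed=0)
        doc = _doc("d", "a")
        assert np.allclose(char_embed(doc, table)[0], table.vectors["a"])

    def test_anagrams_collide_under_mean_pooling(self):
        table = CharEmbeddingTable.random(dim=8, seed=0)
        assert np.allclose(table.token_vector("silent"), table.token_vector("listen"))

    def test_output_dimension_matches_word_dimension(self):
        table = CharEmbeddingTable.random(dim=100, seed=0)
        out = char_embed(_doc("d", "hello world"), table)
        assert out.shape == (2, 100)

    def test_unknown_characters_contribute_zero(self):
        table = CharEmbeddingTable.random(dim=4, seed=0)
        assert (table.token_vector("汉字") == 0).all()


class TestAssemble:
    @pytest.fixture
    def fitted(self, sw_control_docs):
        docs, _ = sw_control_docs
        train = docs[:60]
        tfidf = TfidfModel().fit(train)
        table = train_word_embeddings(train, dim=100, window=3, epochs=1, seed=0)
        char_table = CharEmbeddingTable.random(dim=100, seed=0)
        return train, tfidf, table, char_table

    def test_dimensions_by_combination(self, fitted):
        train, tfidf, table, char_table = fitted
        docs = train[:5]
        a = FeatureAssembler(FeatureCombination.TFIDF, tfidf=tfidf)
        assert a.document_vectors(docs).shape == (5, 100)
        b = FeatureAssembler(FeatureCombination.TFIDF_W2V, tfidf=tfidf,
                             word_table=table)
        assert b.document_vectors(docs).shape == (5, 200)
        c = FeatureAssembler(FeatureCombination.TFIDF_W2V_CHAR2VEC, tfidf=tfidf,
                             word_table=table, char_table=char_table)
        assert c.document_vectors(docs).shape == (5, 300)
        assert c.char_sequences(docs, length=20).shape == (5, 20, 100)
        assert b.side_vectors(docs).shape == (5, 100)

    def test_missing_model_for_combination_raises(self, fitted):
        _, tfidf, _, _ = fitted
        with pytest.raises(ValueError, match="w2v"):
            FeatureAssembler(FeatureCombination.TFIDF_W2V, tfidf=tfidf)

    def test_document_vector_is_order_invariant(self, fitted):
        train, tfidf, table, char_table = fitted
        doc = train[0]
        shuffled = TokenizedDocument(doc.post_id, list(reversed(doc.tokens)),
                                     doc.group)
        asm = FeatureAssembler(FeatureCombination.TFIDF_W2V_CHAR2VEC, tfidf=tfidf,
                               word_table=table, char_table=char_table)
        v1 = asm.document_vectors([doc])
        v2 = asm.document_vectors([shuffled])
        # unigram tf-idf, mean-pooled embeddings: permutation cannot matter
        # except through bigram tf-idf features, which we exclude here
        uni_cols = [i for i, g in enumerate(tfidf.ngrams_) if " " not in g]
        assert np.allclose(v1[0, uni_cols], v2[0, uni_cols], atol=1e-6)
        assert np.allclose(v1[0, 100:], v2[0, 100:], atol=1e-5)


def test_embedding_table_rejects_wrong_shape():
    with pytest.raises(ValueError):
        EmbeddingTable(vectors={"a": np.zeros(3)}, dim=4)
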