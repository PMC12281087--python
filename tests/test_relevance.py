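"""Memory-aware sentence relevance: worked examples, bounds, oracle equality."""

import math

import numpy as np
import pytest

from sentmetrics import (
    DEFAULT_WEIGHTS,
    EQ1_LITERAL_WEIGHTS,
    BagOfWordsEmbedder,
    ContextWindow,
    Document,
    RelevanceWeights,
    Sentence,
    SentenceEmbedding,
    cosine_similarity,
    document_relevance_profile,
    sentence_relevance,
)
from sentmetrics.backends import Capabilities, _BackendBase


def _sent(words, index=0):
    return Sentence(index=index, text=" ".join(words), words=tuple(words))


class FixedEmbedder(_BackendBase):
    """Test embedder mapping sentence text to a preset vector."""

    backend_id = "fixed"
    capabilities = Capabilities(embedding=True)

    def __init__(self, mapping):
        self.mapping = mapping

    def embed(self, sentence):
        return SentenceEmbedding(
            vector=np.asarray(self.mapping[sentence.text], dtype=float),
            backend_id=self.backend_id,
        )


class TestCosine:
    def test_identical_vectors(self):
        a = SentenceEmbedding(np.array([1.0, 2.0, 3.0]), "t")
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = SentenceEmbedding(np.array([1.0, 0.0]), "t")
        b = SentenceEmbedding(np.array([0.0, 1.0]), "t")
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_closed_form_45_degrees(self):
        a = SentenceEmbedding(np.array([1.0, 0.0]), "t")
        b = SentenceEmbedding(np.array([1.0, 1.0]), "t")
        assert cosine_similarity(a, b) == pytest.approx(math.sqrt(2) / 2)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = SentenceEmbedding(rng.normal(size=5), "t")
            b = SentenceEmbedding(rng.normal(size=5), "t")
            assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))

    def test_zero_vector_rejected(self):
        a = SentenceEmbedding(np.zeros(3), "t")
        b = SentenceEmbedding(np.ones(3), "t")
        with pytest.raises(ValueError, match="undefined cosine"):
            cosine_similarity(a, b)

    def test_dimension_mismatch_rejected(self):
        a = SentenceEmbedding(np.ones(3), "t")
        b = SentenceEmbedding(np.ones(4), "t")
        with pytest.raises(ValueError, match="dimension"):
            cosine_similarity(a, b)


class TestSentenceRelevance:
    def test_identical_window_sums_the_weights(self):
        emb = BagOfWordsEmbedder(["cat", "dog"])
        s = [_sent(["cat", "dog"], i) for i in range(4)]
        window = ContextWindow(target=s[2], c1=s[1], c2=s[0], n1=s[3])
        res = sentence_relevance(window, emb)  # defaults {1.0, 0.5, 0.3}
        assert res.value == pytest.approx(1.8)

    def test_orthogonal_neighbors_give_zero(self):
        emb = FixedEmbedder(
            {"t": [1, 0, 0], "c1": [0, 1, 0], "c2": [0, 0, 1], "n1": [0, 1, 1]}
        )
        window = ContextWindow(
            target=Sentence(2, "t", ("t",)),
            c1=Sentence(1, "c1", ("c1",)),
            c2=Sentence(0, "c2", ("c2",)),
            n1=Sentence(3, "n1", ("n1",)),
        )
        assert sentence_relevance(window, emb).value == pytest.approx(0.0)

    def test_hand_computed_two_dimensional_example(self):
        # sims (c1, c2, n1) = (1, 0, sqrt(2)/2) -> 1*1 + 0.5*0 + 0.3*0.7071...
        emb = FixedEmbedder({"t": [1, 0], "c1": [2, 0], "c2": [0, 3], "n1": [1, 1]})
        window = ContextWindow(
            target=Sentence(2, "t", ("t",)),
            c1=Sentence(1, "c1", ("c1",)),
            c2=Sentence(0, "c2", ("c2",)),
            n1=Sentence(3, "n1", ("n1",)),
        )
        res = sentence_relevance(window, emb)
        assert res.value == pytest.approx(1.0 + 0.3 * math.sqrt(2) / 2)
        assert res.value == pytest.approx(1.2121, abs=1e-4)
        assert res.similarities == pytest.approx(
            {"c1": 1.0, "c2": 0.0, "n1": math.sqrt(2) / 2}
        )

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            vecs = {k: rng.normal(size=4) for k in ("t", "c1", "c2", "n1")}
            emb = FixedEmbedder({k: v for k, v in vecs.items()})
            window = ContextWindow(
                target=Sentence(2, "t", ("t",)),
                c1=Sentence(1, "c1", ("c1",)),
                c2=Sentence(0, "c2", ("c2",)),
                n1=Sentence(3, "n1", ("n1",)),
            )
            base = sentence_relevance(window, emb, DEFAULT_WEIGHTS).value
            k = float(rng.uniform(0.1, 5.0))
            scaled = sentence_relevance(window, emb, DEFAULT_WEIGHTS.scaled(k)).value
            assert scaled == pytest.approx(k * base, rel=1e-12, abs=1e-12)

    def test_bound_by_sum_of_present_weights(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            vecs = {k: rng.normal(size=3) for k in ("t", "c1", "c2", "n1")}
            emb = FixedEmbedder(vecs)
            present = {
                k: Sentence(i, k, (k,))
                for i, k in enumerate(("c1", "c2", "n1"))
                if rng.uniform() < 0.7
            }
            window = ContextWindow(target=Sentence(3, "t", ("t",)), **present)
            res = sentence_relevance(window, emb)
            bound = sum(getattr(DEFAULT_WEIGHTS, s) for s in present)
            assert abs(res.value) <= bound + 1e-9

    def test_recency_ordering_of_contributions(self):
        # equal similarities -> c1 contribution >= c2 >= n1 under defaults
        emb = BagOfWordsEmbedder(["w"])
        s = [_sent(["w"], i) for i in range(4)]
        window = ContextWindow(target=s[2], c1=s[1], c2=s[0], n1=s[3])
        res = sentence_relevance(window, emb)
        w = res.weights
        contrib = {k: getattr(w, k) * res.similarities[k] for k in res.similarities}
        assert contrib["c1"] >= contrib["c2"] >= contrib["n1"]

    def test_eq1_literal_preset_swaps_preceding_weights(self):
        assert EQ1_LITERAL_WEIGHTS.c2 == 1.0
        assert EQ1_LITERAL_WEIGHTS.c1 == 0.5
        assert EQ1_LITERAL_WEIGHTS.n1 == 0.3

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RelevanceWeights(-1.0, 0.5, 0.3)
        with pytest.raises(ValueError):
            RelevanceWeights(0.0, 0.0, 0.0)


class TestDocumentProfile:
    def test_single_sentence_document_scores_zero(self):
        emb = BagOfWordsEmbedder(["a"])
        doc = Document("d", "en", (_sent(["a"]),))
        prof = document_relevance_profile(doc, emb)
        assert [r.value for r in prof] == [0.0]

    def test_two_identical_sentences_boundary_enumeration(self):
        emb = BagOfWordsEmbedder(["a", "b"])
        doc = Document("d", "en", (_sent(["a", "b"], 0), _sent(["a", "b"], 1)))
        prof = document_relevance_profile(doc, emb)
        # sentence 0 sees only n1 (weight .3); sentence 1 sees only c1 (weight 1)
        assert [r.value for r in prof] == pytest.approx([0.3, 1.0])

    def test_one_result_per_sentence(self):
        rng = np.random.default_rng(4)
        vocab = ["a", "b", "c", "d", "e"]
        emb = BagOfWordsEmbedder(vocab)
        sents = tuple(
            _sent(list(rng.choice(vocab, size=4)), i) for i in range(7)
        )
        doc = Document("d", "en", sents)
        prof = document_relevance_profile(doc, emb)
        assert [r.sentence_index for r in prof] == list(range(7))

    def test_matches_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(6)
        vocab = ["a", "b", "c", "d", "e", "f"]
        emb = BagOfWordsEmbedder(vocab)
        for n_sent in (2, 3, 4, 5, 6):
            sents = tuple(
                _sent(list(rng.choice(vocab, size=rng.integers(2, 6))), i)
                for i in range(n_sent)
            )
            doc = Document("d", "en", sents)
            # oracle: full pairwise cosine matrix computed independently
            mat = np.array([emb.embed(s).vector for s in sents])
            norms = np.linalg.norm(mat, axis=1)
            cos = (mat @ mat.T) / np.outer(norms, norms)
            w = DEFAULT_WEIGHTS
            for res in document_relevance_profile(doc, emb):
                t = res.sentence_index
                want = 0.0
                if t - 1 >= 0:
                    want += w.c1 * cos[t, t - 1]
                if t - 2 >= 0:
                    want += w.c2 * cos[t, t - 2]
                if t + 1 < n_sent:
                    want += w.n1 * cos[t, t + 1]
                assert res.value == pytest.approx(want, abs=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        vocab = ["a", "b", "c"]
        emb = BagOfWordsEmbedder(vocab)
        doc = Document(
            "d", "en", tuple(_sent(list(rng.choice(vocab, size=3)), i) for i in range(5))
        )
        a = [r.value for r in document_relevance_profile(doc, emb)]
        b = [r.value for r in document_relevance_profile(doc, emb)]
        assert a == b
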