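import math

import numpy as np
import pytest

from emotopic.topic_model import (BowCorpus, KRecord, LdaModel,
                                  coherence_umass, fit_lda,
                                  greedy_topic_match, perplexity, select_k,
                                  summarize_topics, sweep_k)


def bruteforce_perplexity(theta, phi, docs):
    """Independent token-by-token evaluation of the perplexity formula in
    plain Python: exp(-sum_d log p(w_d) / sum_d N_d)."""
    total_ll = 0.0
    n = 0
    for d, words in enumerate(docs):
        for w in words:
            p = sum(theta[d][k] * phi[k][w] for k in range(len(phi)))
            total_ll += math.log(p)
            n += 1
    return math.exp(-total_ll / n), -total_ll / n


def small_corpus(seed=0, M=20, V=12, length=15):
    rng = np.random.default_rng(seed)
    vocab = [f"w{i}" for i in range(V)]
    docs = [rng.integers(0, V, size=length) for _ in range(M)]
    return BowCorpus(vocabulary=vocab, docs=docs)


class TestBowCorpus:
    def test_from_tokenized_indexing(self):
        bow = BowCorpus.from_tokenized([["a", "b", "a"], ["b", "c"]])
        assert bow.M == 2 and bow.V == 3 and bow.n_tokens == 5
        assert bow.vocabulary[0] in ("a", "b")  # highest count first

    def test_min_count_drops_rare_words(self):
        bow = BowCorpus.from_tokenized([["a", "a", "b"]], min_count=2)
        assert bow.vocabulary == ["a"] and bow.n_tokens == 2

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            BowCorpus(vocabulary=["a"], docs=[np.array([1])])


class TestFitLda:
    def test_k1_degeneracy_closed_form(self):
        corpus = small_corpus(seed=1)
        beta = 0.01
        model = fit_lda(corpus, K=1, beta=beta, iterations=20, burn_in=5, seed=3)
        assert np.all(model.theta == 1.0)
        n_w = np.bincount(np.concatenate(corpus.docs), minlength=corpus.V)
        expected = (n_w + beta) / (corpus.n_tokens + corpus.V * beta)
        assert np.max(np.abs(model.phi[0] - expected)) <= 1e-12

    def test_same_seed_is_bit_identical(self):
        corpus = small_corpus(seed=2)
        a = fit_lda(corpus, K=3, iterations=30, burn_in=10, seed=9)
        b = fit_lda(corpus, K=3, iterations=30, burn_in=10, seed=9)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.theta, b.theta)

    def test_rows_are_stochastic(self):
        corpus = small_corpus(seed=3)
        model = fit_lda(corpus, K=4, iterations=30, burn_in=10, seed=1)
        assert np.allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)

    def test_count_conservation_every_sweep(self):
        corpus = small_corpus(seed=4, M=30)
        N_d = corpus.N_d
        n_tokens = corpus.n_tokens

        def check(sweep, ndk, nkw, nk):
            assert np.array_equal(ndk.sum(axis=1), N_d)
            assert np.array_equal(nkw.sum(axis=1), nk)
            assert nk.sum() == n_tokens

        fit_lda(corpus, K=3, iterations=15, burn_in=5, seed=0,
                sweep_callback=check)

    @pytest.mark.parametrize("kwargs,err", [
        ({"K": 0}, "K"),
        ({"K": 2, "iterations": 5, "burn_in": 5}, "burn_in"),
        ({"K": 2, "alpha": -1.0}, "positive"),
    ])
    def test_invalid_arguments(self, kwargs, err):
        with pytest.raises(ValueError, match=err):
            fit_lda(small_corpus(), **kwargs)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(BowCorpus(vocabulary=["a"], docs=[]), K=2)

    def test_save_load_round_trip(self, tmp_path):
        corpus = small_corpus(seed=5)
        model = fit_lda(corpus, K=2, iterations=20, burn_in=5, seed=1)
        model.save(tmp_path / "model")
        loaded = LdaModel.load(tmp_path / "model")
        assert loaded.K == 2 and np.array_equal(loaded.phi, model.phi)


class TestPerplexity:
    @pytest.mark.parametrize("V", [2, 10, 100])
    def test_uniform_model_equals_vocabulary_size(self, V):
        corpus = small_corpus(seed=6, V=V, M=5, length=8)
        model = LdaModel(K=2, alpha=1.0, beta=0.01,
                         phi=np.full((2, V), 1.0 / V),
                         theta=np.full((5, 2), 0.5),
                         z=np.zeros(40, dtype=int), seed=0,
                         iterations=1, burn_in=0)
        perp, log_perp = perplexity(model, corpus)
        assert perp == pytest.approx(V, rel=1e-12)
        assert log_perp == pytest.approx(math.log(V), rel=1e-12)

    def test_degenerate_certain_model_has_perplexity_one(self):
        # each doc repeats a single word; phi/theta put probability 1 on it
        corpus = BowCorpus(vocabulary=["a", "b"],
                           docs=[np.zeros(4, dtype=int), np.ones(3, dtype=int)])
        model = LdaModel(K=2, alpha=1.0, beta=0.01, phi=np.eye(2),
                         theta=np.eye(2), z=np.zeros(7, dtype=int),
                         seed=0, iterations=1, burn_in=0)
        perp, log_perp = perplexity(model, corpus)
        assert perp == pytest.approx(1.0, abs=1e-15)
        assert log_perp == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_on_hand_fixture(self):
        # 2 docs, V=4, hand-fixed phi/theta
        docs = [np.array([0, 1, 2, 0]), np.array([3, 3, 1])]
        corpus = BowCorpus(vocabulary=list("abcd"), docs=docs)
        phi = np.array([[0.4, 0.3, 0.2, 0.1], [0.1, 0.1, 0.2, 0.6]])
        theta = np.array([[0.7, 0.3], [0.2, 0.8]])
        model = LdaModel(K=2, alpha=1.0, beta=0.01, phi=phi, theta=theta,
                         z=np.zeros(7, dtype=int), seed=0, iterations=1,
                         burn_in=0)
        expected = bruteforce_perplexity(theta.tolist(), phi.tolist(),
                                         [d.tolist() for d in docs])
        got = perplexity(model, corpus)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_fitted_model_matches_bruteforce(self):
        corpus = small_corpus(seed=7, M=4, V=6, length=10)
        model = fit_lda(corpus, K=2, iterations=30, burn_in=10, seed=2)
        expected = bruteforce_perplexity(model.theta.tolist(),
                                         model.phi.tolist(),
                                         [d.tolist() for d in corpus.docs])
        assert perplexity(model, corpus)[0] == pytest.approx(expected[0], abs=1e-12)

    def test_perplexity_at_least_one(self):
        corpus = small_corpus(seed=8)
        model = fit_lda(corpus, K=3, iterations=30, burn_in=10, seed=4)
        assert perplexity(model, corpus)[0] >= 1.0


class TestCoherence:
    def make_model(self, phi):
        K, V = phi.shape
        return LdaModel(K=K, alpha=1.0, beta=0.01, phi=phi,
                        theta=np.full((1, K), 1.0 / K),
                        z=np.zeros(1, dtype=int), seed=0, iterations=1,
                        burn_in=0)

    def test_hand_computed_four_doc_corpus(self):
        # docs: {0,1}, {0,1}, {0}, {2}; top-2 words of the topic are 0 then 1
        docs = [np.array([0, 1]), np.array([0, 1]), np.array([0]), np.array([2])]
        corpus = BowCorpus(vocabulary=["a", "b", "c"], docs=docs)
        phi = np.array([[0.6, 0.3, 0.1]])
        # D(a)=3, D(a,b)=2 -> log((2+1)/3) = 0
        expected = math.log((2 + 1) / 3)
        assert coherence_umass(self.make_model(phi), corpus, topN=2) == \
            pytest.approx(expected, abs=1e-12)

    def test_always_cooccurring_pair_is_positive(self):
        docs = [np.array([0, 1]), np.array([0, 1])]
        corpus = BowCorpus(vocabulary=["a", "b"], docs=docs)
        phi = np.array([[0.7, 0.3]])
        assert coherence_umass(self.make_model(phi), corpus, topN=2) > 0

    def test_invariant_under_topic_permutation(self):
        corpus = small_corpus(seed=9, V=8)
        phi = np.random.default_rng(0).dirichlet(np.ones(8), size=3)
        a = coherence_umass(self.make_model(phi), corpus, topN=4)
        b = coherence_umass(self.make_model(phi[::-1].copy()), corpus, topN=4)
        assert a == pytest.approx(b, abs=1e-12)

    def test_never_occurring_word_warns_and_skips(self):
        docs = [np.array([0, 0]), np.array([0])]
        corpus = BowCorpus(vocabulary=["a", "b"], docs=docs)
        phi = np.array([[0.4, 0.6]])  # top word b never occurs
        with pytest.warns(UserWarning, match="never occurs"):
            coherence_umass(self.make_model(phi), corpus, topN=2)


def rec(K, perp, coh):
    return KRecord(K=K, perplexity=perp, log_perplexity=math.log(perp),
                   coherence=coh)


class TestSelectK:
    def test_single_interior_peak(self):
        records = [rec(1, 9, 0.2), rec(2, 7, 0.5), rec(3, 6, 0.3)]
        assert select_k(records) == 2

    def test_monotone_coherence_picks_global_maximum(self):
        records = [rec(1, 9, 0.1), rec(2, 8, 0.2), rec(3, 7, 0.3)]
        assert select_k(records) == 3

    def test_equal_peaks_resolved_by_lower_perplexity(self):
        records = [rec(1, 9, 0.1), rec(2, 7, 0.5), rec(3, 8, 0.2),
                   rec(4, 6, 0.5), rec(5, 9, 0.1)]
        # peaks at K=2 and K=4 with equal coherence; K=4 has lower perplexity
        assert select_k(records) == 4
        # perplexity lower at the smaller K -> the smaller K
        records2 = [rec(1, 9, 0.1), rec(2, 5, 0.5), rec(3, 8, 0.2),
                    rec(4, 6, 0.5), rec(5, 9, 0.1)]
        assert select_k(records2) == 2

    def test_single_record(self):
        assert select_k([rec(1, 5, 0.3)]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_k([])


class TestSweepK:
    def test_records_cover_range_once(self):
        corpus = small_corpus(seed=10)
        sweep = sweep_k(corpus, range(1, 5), iterations=20, burn_in=5, seed=0)
        assert [r.K for r in sweep.records] == [1, 2, 3, 4]

    def test_singleton_range(self):
        corpus = small_corpus(seed=11)
        sweep = sweep_k(corpus, [1], iterations=20, burn_in=5, seed=0)
        assert sweep.selected_K == 1 and len(sweep.records) == 1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            sweep_k(small_corpus(), [], iterations=20, burn_in=5)


class TestSummarize:
    def model_with(self, phi, theta):
        return LdaModel(K=phi.shape[0], alpha=1.0, beta=0.01, phi=phi,
                        theta=theta, z=np.zeros(4, dtype=int), seed=0,
                        iterations=1, burn_in=0)

    def test_intensity_is_mean_theta(self):
        corpus = BowCorpus(vocabulary=["a", "b"],
                           docs=[np.array([0]), np.array([1])])
        model = self.model_with(np.array([[0.5, 0.5], [0.5, 0.5]]),
                                np.array([[1.0, 0.0], [0.0, 1.0]]))
        summary = summarize_topics(model, corpus, topN=2)
        assert np.allclose(summary.intensity, [0.5, 0.5])
        assert summary.intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k1_intensity_is_one(self):
        corpus = BowCorpus(vocabulary=["a"], docs=[np.array([0, 0])])
        model = self.model_with(np.array([[1.0]]), np.array([[1.0]]))
        assert summarize_topics(model, corpus, topN=1).intensity.tolist() == [1.0]

    def test_topn_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        phi = rng.dirichlet(np.ones(10), size=2)
        vocab = [f"w{i}" for i in range(10)]
        corpus = BowCorpus(vocabulary=vocab, docs=[np.arange(10)])
        model = self.model_with(phi, np.array([[0.5, 0.5]]))
        summary = summarize_topics(model, corpus, topN=4)
        for k in range(2):
            expected = sorted(zip(vocab, phi[k]), key=lambda t: -t[1])[:4]
            assert [w for w, _ in summary.topics[k]] == [w for w, _ in expected]
            probs = [p for _, p in summary.topics[k]]
            assert probs == sorted(probs, reverse=True)

    def test_token_share_mode_sums_to_one(self):
        corpus = small_corpus(seed=12)
        model = fit_lda(corpus, K=3, iterations=20, burn_in=5, seed=0)
        summary = summarize_topics(model, corpus, intensity_mode="token_share")
        assert summary.intensity.sum() == pytest.approx(1.0, abs=1e-9)


def test_greedy_topic_match_recovers_permutation():
    rng = np.random.default_rng(4)
    ref = rng.dirichlet(np.ones(20), size=3)
    perm = [2, 0, 1]
    pairs = greedy_topic_match(ref[perm], ref)
    assert all(c == pytest.approx(1.0, abs=1e-12) for _, _, c in pairs)
    assert {(i, j) for i, j, _ in pairs} == {(0, 2), (1, 0), (2, 1)}
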