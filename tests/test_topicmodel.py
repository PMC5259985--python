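import math

import numpy as np
import pytest
from scipy.special import logsumexp
from sklearn.base import clone

from topicmotif import (
    CorrelatedTopicModel,
    DegenerateMatrixError,
    DirichletTopicModel,
    DocTermMatrix,
    GAParams,
    Individual,
    KmerInstance,
    SequenceSet,
    TopicModel,
    VocabularyTooSmallError,
    build_dtm,
    fit_ctm,
    fitness,
    perplexity,
    split_dtm,
)

from conftest import study_params


def _block_matrix():
    """Two disjoint word blocks across two document groups."""
    rng = np.random.default_rng(0)
    X = np.zeros((6, 10), dtype=int)
    X[:3, :5] = rng.integers(5, 15, (3, 5))
    X[3:, 5:] = rng.integers(5, 15, (3, 5))
    return DocTermMatrix([f"w{j}" for j in range(10)], X)


# ---------------------------------------------------------------- build_dtm


def test_build_dtm_counts_with_sliding_windows():
    seqs = SequenceSet([("s1", "ACGTACGT")])
    inst = [KmerInstance(0, 0, "ACGT")]
    dtm = build_dtm(inst, seqs, mismatch_fraction=0.0)
    assert dtm.vocab == ["ACGT"] and dtm.counts.tolist() == [[2]]


def test_build_dtm_deduplicates_vocabulary(planted):
    seqs, _ = planted
    inst = [KmerInstance(0, 0, seqs.sequence(0)[:8])] * 3 + [
        KmerInstance(1, 5, seqs.sequence(1)[5:13])
    ]
    dtm = build_dtm(inst, seqs)
    assert dtm.V == len(set(i.word for i in inst))


def test_build_dtm_absent_word_gives_zero_column():
    seqs = SequenceSet([("s1", "ACGTACGTACGT")])
    inst = [KmerInstance(0, 0, "ACGT"), KmerInstance(0, 0, "A" * 12)]
    dtm = build_dtm(inst, seqs, mismatch_fraction=0.0)
    j = dtm.vocab.index("A" * 12)
    assert dtm.counts[:, j].sum() == 0 and dtm.total > 0


def test_build_dtm_all_zero_is_degenerate():
    seqs = SequenceSet([("s1", "CCCCCCCC")])
    with pytest.raises(DegenerateMatrixError):
        build_dtm([KmerInstance(0, 0, "AAAAAAAA")], seqs, mismatch_fraction=0.0)


def test_build_dtm_matches_counting_oracle(planted, rng):
    from test_kmer import naive_count

    seqs, _ = planted
    words = [seqs.sequence(int(rng.integers(6)))[p : p + 8]
             for p in rng.integers(0, 150, size=5)]
    dtm = build_dtm([KmerInstance(0, 0, w) for w in words], seqs)
    for j, w in enumerate(dtm.vocab):
        for d in range(len(seqs)):
            assert dtm.counts[d, j] == naive_count(w, seqs.sequence(d))


# ---------------------------------------------------------------- split_dtm


def test_split_holds_out_every_fourth_document():
    X = np.arange(24).reshape(6, 4)
    train, test = split_dtm(DocTermMatrix(list("abcd"), X))
    assert train.D == 5 and test.D == 1
    assert np.array_equal(test.counts[0], X[3])


def test_split_few_documents_alternates_tokens_within_each():
    X = np.array([[5, 2, 0], [1, 1, 1]])
    dtm = DocTermMatrix(list("abc"), X)
    train, test = split_dtm(dtm)
    assert np.array_equal(train.counts + test.counts, X)
    for d in range(2):
        total = X[d].sum()
        assert train.counts[d].sum() == (total + 1) // 2


# ------------------------------------------------------------------ fit_ctm


def test_single_topic_beta_is_corpus_frequency():
    X = np.array([[3, 1], [1, 3]])
    model = fit_ctm(DocTermMatrix(["AA", "CC"], X), K=1, smoothing=0.0)
    assert np.allclose(model.beta, [[0.5, 0.5]])
    assert np.allclose(model.doc_topic, 1.0)


def test_fit_is_deterministic_under_seed():
    dtm = _block_matrix()
    a = fit_ctm(dtm, K=2, seed=11)
    b = fit_ctm(dtm, K=2, seed=11)
    assert np.array_equal(a.beta, b.beta)
    assert np.array_equal(a.sigma, b.sigma)


def test_fit_invariants_hold():
    model = fit_ctm(_block_matrix(), K=3, seed=2)
    assert np.allclose(model.beta.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(model.doc_topic.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(model.sigma, model.sigma.T)
    assert (np.linalg.eigvalsh(model.sigma) > -1e-10).all()


def test_objective_is_nondecreasing_across_iterations(rng):
    for _ in range(10):
        D = int(rng.integers(2, 7))
        V = int(rng.integers(3, 41))
        X = rng.integers(0, 6, (D, V))
        if X.sum() == 0:
            continue
        K = int(rng.integers(2, 4))
        if V < K:
            continue
        model = fit_ctm(
            DocTermMatrix([f"w{j}" for j in range(V)], X),
            K=K, seed=int(rng.integers(2**31)),
        )
        hist = np.asarray(model.bound_history)
        assert (np.diff(hist) >= -1e-7 * np.abs(hist[:-1])).all()


def test_two_topics_separate_disjoint_word_blocks():
    model = fit_ctm(_block_matrix(), K=2, seed=0)
    assign = model.beta.argmax(axis=0)
    assert len(set(assign[:5])) == 1
    assert len(set(assign[5:])) == 1
    assert assign[0] != assign[5]


def test_refuses_vocabulary_smaller_than_topic_count():
    dtm = DocTermMatrix(["AA"], np.array([[4]]))
    with pytest.raises(VocabularyTooSmallError):
        fit_ctm(dtm, K=2)


# --------------------------------------------------------------- perplexity


@pytest.mark.parametrize("V", [2, 10, 100])
def test_uniform_single_topic_perplexity_equals_vocab_size(V, rng):
    vocab = [f"w{j}" for j in range(V)]
    model = TopicModel(K=1, vocab=vocab, beta=np.full((1, V), 1.0 / V),
                       mu=np.zeros(0), sigma=np.zeros((0, 0)))
    held = DocTermMatrix(vocab, rng.integers(0, 7, (3, V)))
    assert abs(perplexity(model, held) - V) < 1e-9


def test_perplexity_closed_form_two_words():
    vocab = ["AA", "CC"]
    model = TopicModel(K=1, vocab=vocab, beta=np.array([[0.5, 0.5]]),
                       mu=np.zeros(0), sigma=np.zeros((0, 0)))
    held = DocTermMatrix(vocab, np.array([[3, 1]]))
    assert perplexity(model, held) == pytest.approx(2.0, abs=1e-12)


def test_perplexity_empty_heldout_is_infinite():
    vocab = ["AA"]
    model = TopicModel(K=1, vocab=vocab, beta=np.array([[1.0]]),
                       mu=np.zeros(0), sigma=np.zeros((0, 0)))
    assert perplexity(model, DocTermMatrix(vocab, np.zeros((2, 1), int))) == math.inf


def test_perplexity_rejects_vocabulary_mismatch():
    model = TopicModel(K=1, vocab=["AA"], beta=np.array([[1.0]]),
                       mu=np.zeros(0), sigma=np.zeros((0, 0)))
    with pytest.raises(ValueError):
        perplexity(model, DocTermMatrix(["CC"], np.array([[1]])))


def test_variational_perplexity_matches_monte_carlo_integration():
    """K=2 held-out likelihood vs brute-force logistic-normal integration."""
    rng = np.random.default_rng(7)
    V = 4
    vocab = [f"w{j}" for j in range(V)]
    model = fit_ctm(DocTermMatrix(vocab, rng.integers(0, 8, (6, V))), K=2, seed=3)
    X = rng.integers(0, 4, (2, V))
    perp_var = perplexity(model, DocTermMatrix(vocab, X))

    S = 200_000
    eta = rng.normal(model.mu[0], math.sqrt(model.sigma[0, 0]), size=S)
    theta = np.stack([np.exp(eta), np.ones(S)], axis=1)
    theta /= theta.sum(axis=1, keepdims=True)
    p = theta @ model.beta
    ll = sum(
        logsumexp((X[d][None, :] * np.log(p)).sum(axis=1)) - math.log(S)
        for d in range(X.shape[0])
    )
    perp_mc = math.exp(-ll / X.sum())
    assert perp_var == pytest.approx(perp_mc, rel=0.05)


# ------------------------------------------------------------------ fitness


def test_fitness_infinite_when_words_never_occur():
    seqs = SequenceSet([("s%d" % d, "C" * 50) for d in range(4)])
    ind = Individual([KmerInstance(0, 0, "A" * 8)])
    params = GAParams(k_min=8, k_max=8, K=1, N=2, seed=0)
    assert fitness(ind, seqs, params, np.random.default_rng(0)) == math.inf


def test_fitness_cached_without_touching_rng(planted):
    seqs, truth = planted
    ind = Individual(
        [KmerInstance(seqs.index_of(a.seq_id), a.start, a.site) for a in truth]
    )
    params = study_params()
    rng = np.random.default_rng(0)
    first = fitness(ind, seqs, params, rng)
    state = rng.bit_generator.state
    assert fitness(ind, seqs, params, rng) == first
    assert rng.bit_generator.state == state


def test_planted_vocabulary_beats_random_vocabulary(planted):
    seqs, truth = planted
    params = study_params()
    planted_ind = Individual(
        [KmerInstance(seqs.index_of(a.seq_id), a.start, a.site) for a in truth]
    )
    r = np.random.default_rng(99)
    rand_ind = Individual(
        [
            KmerInstance(d, p, seqs.sequence(d)[p : p + 8])
            for d, p in (
                (int(r.integers(6)), int(r.integers(0, 193))) for _ in range(12)
            )
        ]
    )
    fp = fitness(planted_ind, seqs, params, np.random.default_rng(1))
    fr = fitness(rand_ind, seqs, params, np.random.default_rng(1))
    assert fp < fr


# --------------------------------------------------------------- estimators


def test_ctm_estimator_sklearn_contract():
    est = CorrelatedTopicModel(n_components=2, random_state=0)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    X = _block_matrix().counts
    est.fit(X)
    assert est.components_.shape == (2, 10)
    theta = est.transform(X)
    assert theta.shape == (6, 2)
    assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-8)
    assert np.isfinite(est.perplexity(X))


def test_dirichlet_model_cross_checks_block_structure():
    dtm = _block_matrix()
    ctm = fit_ctm(dtm, K=2, seed=0)
    lda = DirichletTopicModel(n_components=2, random_state=0).fit(dtm.counts)
    a, b = ctm.beta.argmax(axis=0), lda.components_.argmax(axis=0)
    # both model families recover the same vocabulary partition
    same = (a == b).all()
    flipped = (a == 1 - b).all()
    assert same or flipped
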