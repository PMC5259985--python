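"""Correlated topic model (CTM) fitting and held-out perplexity.

The CTM places a logistic-normal prior on per-document topic proportions:
eta ~ N(mu, Sigma) over K-1 free coordinates (the K-th is pinned at 0), and
theta = softmax([eta, 0]).  Each word token draws a topic z ~ Mult(theta)
and a word w ~ Mult(beta_z).  Inference is mean-field variational EM in the
Blei-Lafferty style: q(eta_i) = N(lambda_i, nu_i^2), q(z) multinomial, with
the log-sum-exp term handled through the standard auxiliary bound
E[log sum_k exp(eta_k)] <= zeta^{-1} sum_k E[exp(eta_k)] - 1 + log(zeta).

Every coordinate update either maximizes its conditional bound exactly
(phi, zeta, nu^2) or is safeguarded to never decrease it (lambda, by damped
Newton), so the evidence bound recorded per EM iteration is non-decreasing
up to floating-point noise.

Perplexity of held-out counts omega is exp(-log p(omega) / T) with T the
total token count; for K >= 2 the per-document log-likelihood is the
variational bound, for K = 1 it is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.decomposition import LatentDirichletAllocation

from .kmer import GAParams, Individual, KmerInstance, count_occurrences
from .seqio import SequenceSet

_LOG2PI = math.log(2.0 * math.pi)


class DegenerateMatrixError(ValueError):
    """Raised when a document-term matrix has no counts at all."""


class VocabularyTooSmallError(ValueError):
    """Raised when the vocabulary is smaller than the topic count."""


@dataclass
class DocTermMatrix:
    """Per-document mismatch-tolerant counts of each vocabulary word."""

    vocab: list[str]
    counts: np.ndarray  # (D, V) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.vocab):
            raise ValueError("counts must be (D, V) with V == len(vocab)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocabulary contains duplicate words")

    @property
    def D(self) -> int:
        return self.counts.shape[0]

    @property
    def V(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TopicModel:
    """A fitted topic model (or a manually specified one).

    ``beta`` rows are topic-word distributions; ``mu``/``sigma`` are the
    logistic-normal mean and covariance over the K-1 free coordinates;
    ``doc_topic`` holds posterior topic proportions of the training
    documents; ``loglik`` is the final training objective (evidence bound
    plus the smoothing prior term).
    """

    K: int
    vocab: list[str]
    beta: np.ndarray  # (K, V)
    mu: np.ndarray  # (K-1,)
    sigma: np.ndarray  # (K-1, K-1)
    doc_topic: np.ndarray | None = None
    loglik: float = math.nan
    converged: bool = True
    bound_history: list[float] = field(default_factory=list)


def build_dtm_from_words(
    words: list[str], seqs: SequenceSet, mismatch_fraction: float = 0.25
) -> DocTermMatrix:
    """DTM whose vocabulary is ``words`` deduplicated in insertion order."""
    if not words:
        raise ValueError("empty word list")
    vocab = list(dict.fromkeys(words))
    D = len(seqs)
    counts = np.zeros((D, len(vocab)), dtype=np.int64)
    for j, w in enumerate(vocab):
        for d in range(D):
            counts[d, j] = count_occurrences(w, seqs.encoded(d), mismatch_fraction)
    if counts.sum() == 0:
        raise DegenerateMatrixError("document-term matrix has no counts")
    return DocTermMatrix(vocab, counts)


def build_dtm(
    instances: list[KmerInstance],
    seqs: SequenceSet,
    mismatch_fraction: float = 0.25,
) -> DocTermMatrix:
    """DTM for an individual: one document per sequence, one column per
    distinct instance word, entries counted with the mismatch budget."""
    if not instances:
        raise ValueError("no instances")
    return build_dtm_from_words(
        [inst.word for inst in instances], seqs, mismatch_fraction
    )


def split_dtm(dtm: DocTermMatrix) -> tuple[DocTermMatrix, DocTermMatrix]:
    """Deterministic train/test split for perplexity evaluation.

    With at least four documents, every fourth document (index % 4 == 3)
    is held out (75/25 round-robin by document index).  With fewer, tokens
    within each document alternate into train/test halves, keeping every
    document on both sides.
    """
    D = dtm.D
    if D >= 4:
        test_mask = (np.arange(D) % 4) == 3
        train = DocTermMatrix(dtm.vocab, dtm.counts[~test_mask])
        test = DocTermMatrix(dtm.vocab, dtm.counts[test_mask])
        return train, test
    train = np.zeros_like(dtm.counts)
    test = np.zeros_like(dtm.counts)
    for d in range(D):
        parity = 0
        for j in range(dtm.V):
            n = int(dtm.counts[d, j])
            if n == 0:
                continue
            n_train = (n + (1 if parity == 0 else 0)) // 2
            train[d, j] = n_train
            test[d, j] = n - n_train
            parity = (parity + n) % 2
    return DocTermMatrix(dtm.vocab, train), DocTermMatrix(dtm.vocab, test)


# ---------------------------------------------------------------------------
# Variational EM internals
# ---------------------------------------------------------------------------


def _opt_lambda(lam, mu, inv_sigma, c_free, n_tokens, zeta, nu2):
    """Safeguarded Newton ascent of the lambda-conditional bound.

    f(lam) = -0.5 (lam-mu)' InvS (lam-mu) + c'lam
             - (N/zeta) sum_i exp(lam_i + nu2_i/2)
    is strictly concave; the returned point never has lower f than the
    starting one.
    """
    coef = n_tokens / zeta

    def f(l):
        d = l - mu
        expo = np.clip(l + 0.5 * nu2, None, 700.0)
        return -0.5 * d @ inv_sigma @ d + c_free @ l - coef * np.exp(expo).sum()

    lam = lam.copy()
    f_cur = f(lam)
    for _ in range(25):
        w = coef * np.exp(np.clip(lam + 0.5 * nu2, None, 700.0))
        grad = -inv_sigma @ (lam - mu) + c_free - w
        if np.linalg.norm(grad) < 1e-10 * (1.0 + n_tokens):
            break
        hess = inv_sigma + np.diag(w)  # negative of the true Hessian
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(hess)
        t = 1.0
        improved = False
        for _ in range(40):
            cand = lam + t * step
            f_cand = f(cand)
            if f_cand >= f_cur:
                lam, f_cur, improved = cand, f_cand, True
                break
            t *= 0.5
        if not improved:
            break
    return lam


def _doc_bound(na, lb_act, mu, inv_sigma, logdet, lam, nu2):
    """Per-document evidence bound with phi and zeta at their optima."""
    M = lam.size
    d = lam - mu
    gauss = -0.5 * (
        logdet + M * _LOG2PI + (nu2 * np.diag(inv_sigma)).sum() + d @ inv_sigma @ d
    )
    S = 1.0 + np.exp(np.clip(lam + 0.5 * nu2, None, 700.0)).sum()
    if na.size:
        lam_bar = np.concatenate([lam, [0.0]])
        lse = logsumexp(lam_bar[:, None] + lb_act, axis=0)
        word_term = float(na @ lse) - na.sum() * math.log(S)
    else:
        word_term = 0.0
    entropy = 0.5 * (np.log(2.0 * math.pi * nu2).sum() + M)
    return gauss + word_term + entropy


def _estep_doc(
    n_row, logbeta, mu, inv_sigma, logdet, lam, nu2, rounds=8, tol=1e-8
):
    """Coordinate-ascent update of one document's variational parameters.

    Returns (lam, nu2, active_mask, phi_active, bound).
    """
    act = n_row > 0
    na = n_row[act].astype(float)
    lb = logbeta[:, act]
    n_tokens = float(na.sum())
    K = logbeta.shape[0]
    M = lam.size
    diag_inv = np.diag(inv_sigma)
    lam = lam.copy()
    nu2 = nu2.copy()

    prev = _doc_bound(na, lb, mu, inv_sigma, logdet, lam, nu2)
    for _ in range(rounds):
        # responsibilities and expected topic counts at the current lambda
        if n_tokens > 0:
            lam_bar = np.concatenate([lam, [0.0]])
            a = lam_bar[:, None] + lb
            phi = np.exp(a - logsumexp(a, axis=0))
            c = phi @ na
        else:
            c = np.zeros(K)
        zeta = 1.0 + np.exp(np.clip(lam + 0.5 * nu2, None, 700.0)).sum()
        lam = _opt_lambda(lam, mu, inv_sigma, c[:M], n_tokens, zeta, nu2)
        zeta = 1.0 + np.exp(np.clip(lam + 0.5 * nu2, None, 700.0)).sum()
        coef = n_tokens / zeta
        for i in range(M):
            b = coef * math.exp(min(lam[i], 700.0))
            if b <= 0.0:
                nu2[i] = 1.0 / diag_inv[i]
                continue
            aii = diag_inv[i]

            def h(v, aii=aii, b=b):
                return 1.0 / v - aii - b * math.exp(min(0.5 * v, 350.0))

            hi = 10.0
            while h(hi) > 0 and hi < 1e6:
                hi *= 2.0
            nu2[i] = brentq(h, 1e-12, hi, xtol=1e-12, rtol=1e-10)
        cur = _doc_bound(na, lb, mu, inv_sigma, logdet, lam, nu2)
        if cur - prev <= tol * (1.0 + abs(cur)):
            prev = max(prev, cur)
            break
        prev = cur

    if n_tokens > 0:
        lam_bar = np.concatenate([lam, [0.0]])
        a = lam_bar[:, None] + lb
        phi = np.exp(a - logsumexp(a, axis=0))
    else:
        phi = np.zeros((K, 0))
    return lam, nu2, act, phi, prev


def _safe_log(beta):
    with np.errstate(divide="ignore"):
        return np.log(beta)


def _prior_term(beta, smoothing):
    if smoothing <= 0:
        return 0.0
    return float(smoothing * _safe_log(np.maximum(beta, 1e-300)).sum())


def _fit_ctm_arrays(
    X, K, rng, max_iter=100, tol=1e-4, smoothing=0.01, inner_rounds=8
):
    """Variational EM on a raw (D, V) count matrix.  Returns a dict."""
    X = np.asarray(X, dtype=float)
    D, V = X.shape
    if K == 1:
        col = X.sum(axis=0) + smoothing
        beta = (col / col.sum())[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.where(X > 0, X * _safe_log(beta[0])[None, :], 0.0).sum())
        ll += _prior_term(beta, smoothing)
        return dict(
            beta=beta,
            mu=np.zeros(0),
            sigma=np.zeros((0, 0)),
            doc_topic=np.ones((D, 1)),
            loglik=ll,
            converged=True,
            history=[ll],
        )

    M = K - 1
    # symmetry-broken start: without noise on both the topic-word rows and
    # the per-document means, EM can settle on the degenerate stationary
    # point where every document shares one posterior
    base = X.sum(axis=0) + smoothing
    if base.sum() == 0:
        base = np.ones(V)
    beta = base[None, :] * np.exp(0.5 * rng.standard_normal((K, V)))
    beta /= beta.sum(axis=1, keepdims=True)
    logbeta = _safe_log(beta)

    mu = np.zeros(M)
    sigma = np.eye(M)
    lam = 0.5 * rng.standard_normal((D, M))
    nu2 = np.ones((D, M))

    history: list[float] = []
    converged = False
    prev_obj = None
    for _ in range(max_iter):
        inv_sigma = np.linalg.inv(sigma)
        _, logdet = np.linalg.slogdet(sigma)
        stats = np.zeros((K, V))
        bound = 0.0
        for d in range(D):
            lam[d], nu2[d], act, phi, b_d = _estep_doc(
                X[d], logbeta, mu, inv_sigma, logdet, lam[d], nu2[d],
                rounds=inner_rounds,
            )
            if act.any():
                stats[:, act] += phi * X[d, act]
            bound += b_d
        obj = bound + _prior_term(beta, smoothing)
        history.append(obj)
        if prev_obj is not None and abs(obj - prev_obj) <= tol * (
            abs(prev_obj) + 1e-10
        ):
            converged = True
            break
        prev_obj = obj
        # M-step: exact maximizers
        beta = stats + smoothing
        row = beta.sum(axis=1, keepdims=True)
        zero = row[:, 0] <= 0
        if zero.any():
            beta[zero] = 1.0 / V
            row = beta.sum(axis=1, keepdims=True)
        beta /= row
        logbeta = _safe_log(beta)
        mu = lam.mean(axis=0)
        diff = lam - mu
        sigma = diff.T @ diff / D + np.diag(nu2.mean(axis=0))

    lam_bar = np.concatenate([lam, np.zeros((D, 1))], axis=1)
    doc_topic = np.exp(lam_bar - logsumexp(lam_bar, axis=1, keepdims=True))
    return dict(
        beta=beta,
        mu=mu,
        sigma=sigma,
        doc_topic=doc_topic,
        loglik=history[-1],
        converged=converged,
        history=history,
    )


def _heldout_bound(X, beta, mu, sigma, rounds=50):
    """Sum of per-document variational bounds for new documents."""
    X = np.asarray(X, dtype=float)
    logbeta = _safe_log(beta)
    M = mu.size
    inv_sigma = np.linalg.inv(sigma)
    _, logdet = np.linalg.slogdet(sigma)
    total = 0.0
    doc_topic = np.zeros((X.shape[0], beta.shape[0]))
    for d in range(X.shape[0]):
        lam0 = mu.copy()
        nu20 = np.diag(sigma).copy()
        lam_d, nu2_d, _, _, b_d = _estep_doc(
            X[d], logbeta, mu, inv_sigma, logdet, lam0, nu20,
            rounds=rounds, tol=1e-10,
        )
        total += b_d
        lam_bar = np.concatenate([lam_d, [0.0]])
        doc_topic[d] = np.exp(lam_bar - logsumexp(lam_bar))
    return total, doc_topic


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------


class CorrelatedTopicModel(BaseEstimator):
    """Correlated topic model fitted by variational EM.

    Parameters
    ----------
    n_components : int
        Number of topics K.
    max_iter, tol : EM stopping rule (relative change of the evidence bound).
    smoothing : Dirichlet-style pseudocount added to topic-word counts in the
        M-step; keeps held-out words at non-zero probability.
    inner_rounds : coordinate-ascent sweeps per document per EM iteration.
    random_state : seed for the topic-word initialization.

    Attributes (after ``fit``)
    --------------------------
    components_ : (K, V) topic-word probabilities (rows sum to 1).
    mean_, covariance_ : logistic-normal parameters over K-1 coordinates.
    doc_topic_ : (D, K) posterior topic proportions of the training docs.
    bound_ : final training objective; ``bound_history_`` per-iteration
        values (non-decreasing).
    """

    def __init__(
        self,
        n_components: int = 3,
        max_iter: int = 100,
        tol: float = 1e-4,
        smoothing: float = 0.01,
        inner_rounds: int = 8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.smoothing = smoothing
        self.inner_rounds = inner_rounds
        self.random_state = random_state

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D count matrix")
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.sum() == 0:
            raise DegenerateMatrixError("count matrix has no tokens")
        if X.shape[1] < self.n_components:
            raise VocabularyTooSmallError(
                f"vocabulary size {X.shape[1]} < K={self.n_components}"
            )
        rng = np.random.default_rng(self.random_state)
        res = _fit_ctm_arrays(
            X,
            self.n_components,
            rng,
            max_iter=self.max_iter,
            tol=self.tol,
            smoothing=self.smoothing,
            inner_rounds=self.inner_rounds,
        )
        self.components_ = res["beta"]
        self.mean_ = res["mu"]
        self.covariance_ = res["sigma"]
        self.doc_topic_ = res["doc_topic"]
        self.bound_ = res["loglik"]
        self.bound_history_ = res["history"]
        self.converged_ = res["converged"]
        self.n_iter_ = len(res["history"])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        if self.n_components == 1:
            return np.ones((X.shape[0], 1))
        _, doc_topic = self._heldout(X)
        return doc_topic

    def _heldout(self, X):
        return _heldout_bound(
            X, self.components_, self.mean_, self.covariance_
        )

    def score(self, X, y=None):
        """Held-out log-likelihood (variational bound; exact for K=1)."""
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        if self.n_components == 1:
            logb = _safe_log(self.components_[0])
            with np.errstate(invalid="ignore"):
                return float(np.where(X > 0, X * logb[None, :], 0.0).sum())
        total, _ = self._heldout(X)
        return total

    def perplexity(self, X):
        X = self._validate(X)
        T = X.sum()
        if T == 0:
            return math.inf
        ll = self.score(X)
        if not np.isfinite(ll):
            return math.inf
        arg = -ll / T
        return math.inf if arg > 700 else float(np.exp(arg))


class DirichletTopicModel(BaseEstimator):
    """Dirichlet-prior topic model (LDA) behind the same surface.

    A faster, simpler member of the same model family used as an internal
    cross-check for the CTM; inference is delegated to scikit-learn's
    variational LDA.
    """

    def __init__(
        self, n_components: int = 3, max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.sum() == 0:
            raise DegenerateMatrixError("count matrix has no tokens")
        if X.shape[1] < self.n_components:
            raise VocabularyTooSmallError(
                f"vocabulary size {X.shape[1]} < K={self.n_components}"
            )
        self._lda = LatentDirichletAllocation(
            n_components=self.n_components,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(X)
        comp = self._lda.components_
        self.components_ = comp / comp.sum(axis=1, keepdims=True)
        self.doc_topic_ = self._lda.transform(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return self._lda.transform(np.asarray(X, dtype=float))

    def perplexity(self, X):
        X = np.asarray(X, dtype=float)
        if X.sum() == 0:
            return math.inf
        return float(self._lda.perplexity(X))


def fit_ctm(
    dtm: DocTermMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    smoothing: float = 0.01,
) -> TopicModel:
    """Fit a CTM to a document-term matrix.

    Deterministic given ``seed``.  Refuses vocabularies smaller than K and
    matrices with no counts.
    """
    if dtm.total == 0:
        raise DegenerateMatrixError("document-term matrix has no counts")
    if dtm.V < K:
        raise VocabularyTooSmallError(f"V={dtm.V} < K={K}")
    est = CorrelatedTopicModel(
        n_components=K, max_iter=max_iter, tol=tol, smoothing=smoothing,
        random_state=seed,
    ).fit(dtm.counts)
    return TopicModel(
        K=K,
        vocab=list(dtm.vocab),
        beta=est.components_,
        mu=est.mean_,
        sigma=est.covariance_,
        doc_topic=est.doc_topic_,
        loglik=est.bound_,
        converged=est.converged_,
        bound_history=list(est.bound_history_),
    )


def perplexity(model: TopicModel, heldout: DocTermMatrix) -> float:
    """exp(-L/T) on held-out counts; +inf when T = 0.

    ``L`` is the held-out log-likelihood (exact for K=1, otherwise the
    variational bound used for the document-topic integration); ``T`` the
    total held-out token count.
    """
    if list(model.vocab) != list(heldout.vocab):
        raise ValueError("held-out vocabulary differs from the model's")
    T = heldout.total
    if T == 0:
        return math.inf
    X = heldout.counts.astype(float)
    if model.K == 1:
        logb = _safe_log(model.beta[0])
        with np.errstate(invalid="ignore"):
            ll = float(np.where(X > 0, X * logb[None, :], 0.0).sum())
    else:
        ll, _ = _heldout_bound(X, model.beta, model.mu, model.sigma)
    if not np.isfinite(ll):
        return math.inf
    arg = -ll / T
    return math.inf if arg > 700 else float(np.exp(arg))


def fitness(
    individual: Individual,
    seqs: SequenceSet,
    params: GAParams,
    rng: np.random.Generator,
) -> float:
    """Held-out CTM perplexity of an individual's vocabulary (cached).

    Builds the DTM over the full sequence set, splits train/test, fits the
    CTM on the training side and scores the test side.  Degenerate inputs
    (empty individual, all-zero matrix, vocabulary smaller than K, empty
    split) yield +inf rather than an exception so the GA loop stays total.
    """
    if individual.fitness is not None:
        return individual.fitness
    value = math.inf
    if individual.instances:
        try:
            dtm = build_dtm(individual.instances, seqs, params.mismatch_fraction)
            train, test = split_dtm(dtm)
            if train.total > 0 and test.total > 0 and dtm.V >= params.K:
                seed = int(rng.integers(2**31))
                model = fit_ctm(train, params.K, seed=seed)
                value = perplexity(model, test)
        except (DegenerateMatrixError, VocabularyTooSmallError, ValueError):
            value = math.inf
    individual.fitness = value
    return value
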