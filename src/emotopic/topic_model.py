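"""Latent Dirichlet allocation by collapsed Gibbs sampling, with
perplexity and UMass coherence for topic-number selection.

Model
-----
Each document d mixes K topics with weights θ_d ~ Dirichlet(α); each topic
k is a distribution φ_k over the V vocabulary words, φ_k ~ Dirichlet(β).
Inference integrates θ and φ out and resamples each token's topic
assignment z_i from the standard collapsed conditional

    P(z_i = k | z_-i, w)  ∝  (n_dk^-i + α) · (n_kw_i^-i + β) / (n_k^-i + Vβ)

where n_dk, n_kw, n_k are the current assignment counts excluding token i.
Point estimates are posterior means from the post-burn-in counts:

    φ_kw = (n̄_kw + β) / (n̄_k + Vβ),   θ_dk = (n̄_dk + α) / (N_d + Kα).

Scoring
-------
perplexity(D) = exp(− Σ_d log p(w_d) / Σ_d N_d) with
log p(w_d) = Σ_{i∈d} log Σ_k θ_dk φ_kw_i, evaluated on the training corpus
by default.  Coherence is UMass: mean over topics of
Σ_{j<i} log[(D(w_i, w_j) + 1) / D(w_j)] over each topic's top-N words,
where D counts documents containing the word(s).  The operating K is the
coherence local maximum with the lowest perplexity (global coherence
maximum when no interior peak exists; ties to the smallest K).

Defaults α = 50/K, β = 0.01, 1000 sweeps with 200 burn-in are the common
literature choices; all are configurable.  Identical (corpus, config,
seed) yields bit-identical models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# corpus container


@dataclass
class BowCorpus:
    """Bag-of-words corpus: an indexed vocabulary and per-document word-index
    occurrence lists (order within a document is irrelevant to the model)."""

    vocabulary: list[str]
    docs: list[np.ndarray]

    def __post_init__(self) -> None:
        V = len(self.vocabulary)
        self.docs = [np.asarray(d, dtype=np.int64) for d in self.docs]
        for j, d in enumerate(self.docs):
            if d.size and (d.min() < 0 or d.max() >= V):
                raise ValueError(f"doc {j}: word index out of range [0, {V})")

    @property
    def M(self) -> int:
        return len(self.docs)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def N_d(self) -> np.ndarray:
        return np.array([len(d) for d in self.docs], dtype=np.int64)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.docs))

    @classmethod
    def from_tokenized(
        cls,
        token_lists: Sequence[Sequence[str]],
        min_count: int = 1,
        vocabulary: Sequence[str] | None = None,
    ) -> "BowCorpus":
        """Build from token lists.  Without an explicit vocabulary, words
        with total count >= ``min_count`` are indexed by (count desc, word
        asc) for a deterministic ordering; out-of-vocabulary tokens are
        dropped."""
        if vocabulary is None:
            counts: dict[str, int] = {}
            for toks in token_lists:
                for t in toks:
                    counts[t] = counts.get(t, 0) + 1
            vocabulary = [w for w, c in sorted(counts.items(),
                                               key=lambda kv: (-kv[1], kv[0]))
                          if c >= min_count]
        index = {w: i for i, w in enumerate(vocabulary)}
        docs = [np.array([index[t] for t in toks if t in index], dtype=np.int64)
                for toks in token_lists]
        return cls(vocabulary=list(vocabulary), docs=docs)

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        doc_ids = np.concatenate(
            [np.full(len(d), j, dtype=np.int64) for j, d in enumerate(self.docs)]
        ) if self.docs else np.empty(0, dtype=np.int64)
        word_ids = (np.concatenate(self.docs)
                    if self.docs else np.empty(0, dtype=np.int64))
        return doc_ids, word_ids


# ---------------------------------------------------------------------------
# Gibbs kernel (numba)


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial numba shim
    np.random.seed(seed)


@njit(cache=True)
def _init_assignments(doc_ids, word_ids, M, V, K):
    n = doc_ids.shape[0]
    z = np.empty(n, np.int64)
    ndk = np.zeros((M, K), np.int64)
    nkw = np.zeros((K, V), np.int64)
    nk = np.zeros(K, np.int64)
    for i in range(n):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, word_ids[i]] += 1
        nk[k] += 1
    return z, ndk, nkw, nk


@njit(cache=True)
def _gibbs_sweep(doc_ids, word_ids, z, ndk, nkw, nk, alpha, beta, K, V):
    n = doc_ids.shape[0]
    Vbeta = V * beta
    p = np.empty(K, np.float64)
    for i in range(n):
        d = doc_ids[i]
        w = word_ids[i]
        k = z[i]
        ndk[d, k] -= 1
        nkw[k, w] -= 1
        nk[k] -= 1
        total = 0.0
        for kk in range(K):
            val = (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + Vbeta)
            p[kk] = val
            total += val
        u = np.random.random() * total
        acc = 0.0
        knew = K - 1
        for kk in range(K):
            acc += p[kk]
            if u < acc:
                knew = kk
                break
        z[i] = knew
        ndk[d, knew] += 1
        nkw[knew, w] += 1
        nk[knew] += 1


# ---------------------------------------------------------------------------
# model


@dataclass
class LdaModel:
    K: int
    alpha: float
    beta: float
    phi: np.ndarray      # K x V, rows sum to 1
    theta: np.ndarray    # M x K, rows sum to 1
    z: np.ndarray        # final per-token assignments (flattened corpus order)
    seed: int
    iterations: int
    burn_in: int

    def save(self, path: str | Path) -> None:
        """Serialize to ``<path>.json`` (scalars) + ``<path>.npz`` (arrays)."""
        path = Path(path)
        path.with_suffix(".json").write_text(json.dumps(
            {"K": self.K, "alpha": self.alpha, "beta": self.beta,
             "seed": self.seed, "iterations": self.iterations,
             "burn_in": self.burn_in}, indent=2))
        np.savez(path.with_suffix(".npz"), phi=self.phi, theta=self.theta, z=self.z)

    @classmethod
    def load(cls, path: str | Path) -> "LdaModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrs = np.load(path.with_suffix(".npz"))
        return cls(phi=arrs["phi"], theta=arrs["theta"], z=arrs["z"], **meta)


def fit_lda(
    corpus: BowCorpus,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    sweep_callback: Callable[[int, np.ndarray, np.ndarray, np.ndarray], None] | None = None,
) -> LdaModel:
    """Fit LDA by collapsed Gibbs sampling.

    ``alpha`` defaults to 50/K.  ``sweep_callback(sweep, ndk, nkw, nk)`` is
    invoked after every sweep with live views of the count arrays (read-only
    use; intended for diagnostics such as count-conservation checks).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if corpus.M == 0 or corpus.n_tokens == 0:
        raise ValueError("corpus must contain at least one token")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")

    doc_ids, word_ids = corpus.flatten()
    M, V = corpus.M, corpus.V
    _seed_rng(seed)
    z, ndk, nkw, nk = _init_assignments(doc_ids, word_ids, M, V, K)
    ndk_acc = np.zeros_like(ndk)
    nkw_acc = np.zeros_like(nkw)
    kept = 0
    for sweep in range(iterations):
        _gibbs_sweep(doc_ids, word_ids, z, ndk, nkw, nk, alpha, beta, K, V)
        if sweep_callback is not None:
            sweep_callback(sweep, ndk, nkw, nk)
        if sweep >= burn_in:
            ndk_acc += ndk
            nkw_acc += nkw
            kept += 1

    ndk_mean = ndk_acc / kept
    nkw_mean = nkw_acc / kept
    nk_mean = nkw_mean.sum(axis=1)
    phi = (nkw_mean + beta) / (nk_mean[:, None] + V * beta)
    theta = (ndk_mean + alpha) / (corpus.N_d[:, None] + K * alpha)
    return LdaModel(K=K, alpha=alpha, beta=beta, phi=phi, theta=theta, z=z,
                    seed=seed, iterations=iterations, burn_in=burn_in)


# ---------------------------------------------------------------------------
# scoring


def perplexity(model: LdaModel, corpus: BowCorpus,
               theta: np.ndarray | None = None) -> tuple[float, float]:
    """Corpus perplexity and its log.

    ``log p(w_d) = Σ_i log Σ_k θ_dk φ_k,w_i``;
    ``log_perplexity = − Σ_d log p(w_d) / Σ_d N_d``;
    ``perplexity = exp(log_perplexity)``.

    Uses the model's own θ (training-corpus evaluation) unless an inferred
    ``theta`` for a held-out corpus is supplied (see :func:`infer_theta`).
    """
    th = model.theta if theta is None else theta
    if th.shape[0] != corpus.M:
        raise ValueError("theta rows do not match corpus documents")
    if model.phi.shape[1] != corpus.V:
        raise ValueError("model and corpus vocabulary sizes differ")
    total_ll = 0.0
    for d, words in enumerate(corpus.docs):
        if len(words) == 0:
            continue
        tok_p = th[d] @ model.phi[:, words]
        if np.any(tok_p <= 0):
            raise ValueError("zero-probability token under the model")
        total_ll += float(np.log(tok_p).sum())
    n = corpus.n_tokens
    log_perp = -total_ll / n
    return float(np.exp(log_perp)), float(log_perp)


def infer_theta(model: LdaModel, corpus: BowCorpus, iterations: int = 50) -> np.ndarray:
    """Fold-in θ for a held-out corpus under fixed φ by fixed-point iteration
    on the per-token topic responsibilities."""
    M, K = corpus.M, model.K
    theta = np.full((M, K), 1.0 / K)
    for d, words in enumerate(corpus.docs):
        if len(words) == 0:
            continue
        phi_w = model.phi[:, words]          # K x N_d
        th = np.full(K, 1.0 / K)
        for _ in range(iterations):
            resp = th[:, None] * phi_w
            resp /= resp.sum(axis=0, keepdims=True)
            th = (resp.sum(axis=1) + model.alpha) / (len(words) + K * model.alpha)
        theta[d] = th
    return theta


def top_words(model: LdaModel, k: int, topN: int) -> np.ndarray:
    """Indices of topic ``k``'s top-N words by φ, ties to the lower index."""
    order = np.lexsort((np.arange(model.phi.shape[1]), -model.phi[k]))
    return order[:topN]


def coherence_umass(model: LdaModel, corpus: BowCorpus, topN: int = 10) -> float:
    """UMass coherence averaged over topics.

    For each topic's top-N words ranked w_1 (most probable) .. w_N, sums
    log[(D(w_i, w_j) + 1) / D(w_j)] over pairs j < i, where D() counts
    documents of ``corpus`` containing the word(s).  Pairs whose
    conditioning word never occurs are excluded with a warning.
    """
    if topN < 2:
        raise ValueError("topN must be >= 2")
    doc_sets: dict[int, set[int]] = {}
    for d, words in enumerate(corpus.docs):
        for w in set(words.tolist()):
            doc_sets.setdefault(w, set()).add(d)
    per_topic = np.empty(model.K)
    for k in range(model.K):
        top = top_words(model, k, topN)
        score = 0.0
        for i in range(1, len(top)):
            for j in range(i):
                wi, wj = int(top[i]), int(top[j])
                dj = doc_sets.get(wj, set())
                if not dj:
                    warnings.warn(
                        f"coherence: word index {wj} never occurs; pair skipped")
                    continue
                dij = len(doc_sets.get(wi, set()) & dj)
                score += np.log((dij + 1) / len(dj))
        per_topic[k] = score
    return float(per_topic.mean())


# ---------------------------------------------------------------------------
# K selection


@dataclass(frozen=True)
class KRecord:
    K: int
    perplexity: float
    log_perplexity: float
    coherence: float


@dataclass
class KSweepResult:
    records: list[KRecord]
    selected_K: int
    selection_rule: str = ("highest-coherence interior local maximum; "
                           "coherence ties broken by lower perplexity; "
                           "global coherence maximum if no interior peak; "
                           "remaining ties to smallest K")

    def to_rows(self) -> list[dict]:
        return [{"K": r.K, "perplexity": r.perplexity,
                 "log_perplexity": r.log_perplexity, "coherence": r.coherence}
                for r in self.records]


def select_k(records: Sequence[KRecord]) -> int:
    """Operating-K rule (peak consistency with slowly declining perplexity).

    Among the interior local maxima of the coherence-vs-K curve, take the K
    with the highest coherence; exact coherence ties break by lower
    perplexity (training perplexity declines with K, so the smaller, less
    complex K wins a tie).  With no interior peak the global coherence
    maximum is used.  Remaining ties go to the smallest K.

    Ranking peaks by perplexity instead would always favour the largest-K
    wiggle of the coherence curve, since training perplexity decreases
    monotonically in K; the coherence peak itself is the selection signal.
    """
    if not records:
        raise ValueError("need at least one record")
    recs = sorted(records, key=lambda r: r.K)
    c = [r.coherence for r in recs]
    peaks = [i for i in range(1, len(recs) - 1)
             if c[i] > c[i - 1] and c[i] > c[i + 1]]
    candidates = peaks if peaks else range(len(recs))
    best = min(candidates, key=lambda i: (-c[i], recs[i].perplexity, recs[i].K))
    return recs[best].K


def sweep_k(
    corpus: BowCorpus,
    k_range: Iterable[int],
    alpha: float | None = None,
    beta: float = 0.01,
    iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    topN: int = 10,
) -> KSweepResult:
    """Fit one model per K (each re-seeded with ``seed + K`` so fits are
    independent but deterministic), score perplexity and coherence, and
    apply :func:`select_k`."""
    ks = sorted(set(k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    records = []
    for K in ks:
        model = fit_lda(corpus, K, alpha=alpha, beta=beta,
                        iterations=iterations, burn_in=burn_in, seed=seed + K)
        perp, log_perp = perplexity(model, corpus)
        coh = coherence_umass(model, corpus, topN=max(2, min(topN, corpus.V)))
        records.append(KRecord(K=K, perplexity=perp, log_perplexity=log_perp,
                               coherence=coh))
    return KSweepResult(records=records, selected_K=select_k(records))


def greedy_topic_match(phi_fit: np.ndarray,
                       phi_ref: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedily pair fitted topic-word rows with reference rows by cosine
    similarity: repeatedly take the best remaining (fit, ref) pair.  Returns
    (fit_index, ref_index, cosine) triples, one per reference row (requires
    at least as many fitted rows as reference rows)."""
    if phi_fit.shape[0] < phi_ref.shape[0]:
        raise ValueError("need at least as many fitted topics as reference topics")
    a = phi_fit / np.linalg.norm(phi_fit, axis=1, keepdims=True)
    b = phi_ref / np.linalg.norm(phi_ref, axis=1, keepdims=True)
    sim = a @ b.T
    pairs = []
    free_fit = set(range(phi_fit.shape[0]))
    free_ref = set(range(phi_ref.shape[0]))
    while free_ref:
        i, j = max(((i, j) for i in free_fit for j in free_ref),
                   key=lambda ij: sim[ij])
        pairs.append((i, j, float(sim[i, j])))
        free_fit.discard(i)
        free_ref.discard(j)
    return sorted(pairs, key=lambda p: p[1])


# ---------------------------------------------------------------------------
# summaries


@dataclass
class TopicSummary:
    """Per-topic top-N (keyword, probability) pairs plus the topic-intensity
    vector (corpus-level topic shares, summing to 1)."""

    topics: list[list[tuple[str, float]]]
    intensity: np.ndarray
    intensity_mode: str = "mean_theta"


def summarize_topics(
    model: LdaModel,
    corpus: BowCorpus,
    topN: int = 10,
    intensity_mode: str = "mean_theta",
) -> TopicSummary:
    """Top-N keywords with probabilities per topic, plus topic intensity.

    Intensity is the mean document-topic weight (``mean_theta``, default) or
    the share of tokens assigned to each topic in the final Gibbs state
    (``token_share``); both sum to 1 across topics.
    """
    if topN < 1:
        raise ValueError("topN must be >= 1")
    topics = []
    for k in range(model.K):
        idx = top_words(model, k, min(topN, corpus.V))
        topics.append([(corpus.vocabulary[int(w)], float(model.phi[k, w]))
                       for w in idx])
    if intensity_mode == "mean_theta":
        intensity = model.theta.mean(axis=0)
    elif intensity_mode == "token_share":
        intensity = np.bincount(model.z, minlength=model.K) / len(model.z)
    else:
        raise ValueError(f"unknown intensity_mode {intensity_mode!r}")
    return TopicSummary(topics=topics, intensity=intensity,
                        intensity_mode=intensity_mode)
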