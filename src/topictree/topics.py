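"""Per-locus topic models on k-mer corpora.

Each locus is an independent LDA problem: documents are the taxa (or pooled
populations), words are non-overlapping k-mers. Under LDA, document d mixes
M latent topics with Dirichlet-distributed proportions theta_d ~ Dir(alpha),
each topic m is a distribution over the vocabulary beta_m ~ Dir(eta), and
every word token draws a topic z then a word w | z. The fitted per-document
topic frequencies theta_d are the continuous characters handed to tree
inference; beta is retained for inspection and coherence scoring.

Fitting uses batch variational Bayes (the standard mean-field coordinate
ascent on the variational Dirichlet parameters gamma and lambda), fully
vectorized over documents — corpora here are tiny (a handful of documents,
a few hundred words) but number in the tens of thousands across loci and
bootstrap replicates, so per-fit overhead matters more than asymptotics.
With a fixed seed the fit is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, psi

from .kmers import KmerCorpus

__all__ = [
    "Vocabulary",
    "LdaConfig",
    "TopicFit",
    "build_vocabulary",
    "doc_term_matrix",
    "fit_lda",
    "umass_coherence",
    "select_num_topics",
]


@dataclass
class LdaConfig:
    """Topic-model settings.

    num_topics: M, fixed at 5 by default — adequate across dataset scales
        and cheap; use select_num_topics for a coherence-guided choice.
    alpha/eta: symmetric Dirichlet priors; None means 1/M.
    passes: variational EM sweeps (E-step run to convergence inside each).
    min_corpus_freq / min_doc_freq: vocabulary pruning thresholds; words
        below either threshold are removed before fitting.
    """

    num_topics: int = 5
    alpha: float | None = None
    eta: float | None = None
    passes: int = 50
    seed: int | None = None
    min_corpus_freq: int = 2
    min_doc_freq: int = 1

    def __post_init__(self) -> None:
        if self.num_topics < 2:
            raise ValueError("num_topics must be >= 2")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        for name in ("alpha", "eta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 1.0 / self.num_topics

    def effective_eta(self) -> float:
        return self.eta if self.eta is not None else 1.0 / self.num_topics


@dataclass
class Vocabulary:
    """Pruned k-mer -> dense id map for one locus."""

    locus_id: str
    index: dict[str, int]
    corpus_freq: np.ndarray  # total count per word id
    doc_freq: np.ndarray  # number of documents containing each word id

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def words(self) -> list[str]:
        return list(self.index)


@dataclass
class TopicFit:
    """Fitted LDA for one locus: theta (D x M), beta (M x V), ELBO bound."""

    locus_id: str
    labels: list[str]
    theta: np.ndarray
    beta: np.ndarray
    bound: float
    vocabulary: Vocabulary | None = None

    @property
    def num_topics(self) -> int:
        return self.theta.shape[1]


def build_vocabulary(corpus: KmerCorpus, config: LdaConfig) -> Vocabulary:
    """Assign dense ids in first-occurrence order, pruning words whose total
    count < min_corpus_freq or document frequency < min_doc_freq."""
    if not corpus.documents:
        raise ValueError(f"empty corpus for locus {corpus.locus_id!r}")
    totals: dict[str, int] = {}
    dfreq: dict[str, int] = {}
    for counts in corpus.documents.values():
        for word, c in counts.items():
            totals[word] = totals.get(word, 0) + c
            dfreq[word] = dfreq.get(word, 0) + 1
    index: dict[str, int] = {}
    cf: list[int] = []
    df: list[int] = []
    for word, total in totals.items():
        if total >= config.min_corpus_freq and dfreq[word] >= config.min_doc_freq:
            index[word] = len(index)
            cf.append(total)
            df.append(dfreq[word])
    if not index:
        raise ValueError(
            f"locus {corpus.locus_id!r}: vocabulary empty after pruning "
            f"(min_corpus_freq={config.min_corpus_freq}, "
            f"min_doc_freq={config.min_doc_freq}); use a smaller k or lower "
            f"thresholds"
        )
    return Vocabulary(
        locus_id=corpus.locus_id,
        index=index,
        corpus_freq=np.asarray(cf, dtype=np.int64),
        doc_freq=np.asarray(df, dtype=np.int64),
    )


def doc_term_matrix(corpus: KmerCorpus, vocab: Vocabulary) -> np.ndarray:
    """Dense D x V count matrix in document (label) order."""
    X = np.zeros((len(corpus.documents), vocab.size))
    for d, counts in enumerate(corpus.documents.values()):
        for word, c in counts.items():
            j = vocab.index.get(word)
            if j is not None:
                X[d, j] = c
    return X


def _dirichlet_expectation(x: np.ndarray) -> np.ndarray:
    """E[log p] for rows of Dirichlet parameters."""
    return psi(x) - psi(x.sum(axis=-1, keepdims=True))


def _vb_lda(
    X: np.ndarray,
    M: int,
    alpha: float,
    eta: float,
    passes: int,
    rng: np.random.Generator,
    inner_max: int = 60,
    inner_tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch variational Bayes for LDA; returns (gamma D x M, lam M x V)."""
    D, V = X.shape
    lam = rng.gamma(100.0, 0.01, (M, V))
    gamma = rng.gamma(100.0, 0.01, (D, M))
    for _ in range(passes):
        exp_elog_beta = np.exp(_dirichlet_expectation(lam))
        # E-step: fixed-point updates of gamma, vectorized over documents
        for _ in range(inner_max):
            last = gamma
            exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
            phinorm = exp_elog_theta @ exp_elog_beta + 1e-100
            gamma = alpha + exp_elog_theta * ((X / phinorm) @ exp_elog_beta.T)
            if np.abs(gamma - last).mean() < inner_tol:
                break
        exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
        phinorm = exp_elog_theta @ exp_elog_beta + 1e-100
        # M-step: expected topic-word counts
        lam = eta + exp_elog_beta * (exp_elog_theta.T @ (X / phinorm))
    return gamma, lam


def _elbo(X, gamma, lam, alpha, eta) -> float:
    """Variational lower bound on log p(w | alpha, eta) (Hoffman et al. form)."""
    D, M = gamma.shape
    V = lam.shape[1]
    elog_theta = _dirichlet_expectation(gamma)
    elog_beta = _dirichlet_expectation(lam)
    score = float(
        np.sum(X * np.log(np.exp(elog_theta) @ np.exp(elog_beta) + 1e-100))
    )
    score += float(
        np.sum((alpha - gamma) * elog_theta)
        + np.sum(gammaln(gamma))
        - np.sum(gammaln(gamma.sum(axis=1)))
        + D * (gammaln(M * alpha) - M * gammaln(alpha))
    )
    score += float(
        np.sum((eta - lam) * elog_beta)
        + np.sum(gammaln(lam))
        - np.sum(gammaln(lam.sum(axis=1)))
        + M * (gammaln(V * eta) - V * gammaln(eta))
    )
    return score


def fit_lda(
    corpus: KmerCorpus,
    vocab: Vocabulary | None = None,
    config: LdaConfig | None = None,
) -> TopicFit:
    """Fit LDA to one locus; theta rows are renormalized posterior-mean topic
    frequencies. Documents left with zero tokens after pruning get a uniform
    theta row (and a warning) so the downstream character matrix stays
    rectangular."""
    config = config or LdaConfig()
    if vocab is None:
        vocab = build_vocabulary(corpus, config)
    labels = corpus.labels
    if len(labels) < 2:
        raise ValueError(f"locus {corpus.locus_id!r}: need >= 2 documents")
    M = config.num_topics
    if vocab.size < M:
        warnings.warn(
            f"locus {corpus.locus_id!r}: vocabulary size {vocab.size} < "
            f"num_topics {M}; topic frequencies may be poorly determined"
        )
    X = doc_term_matrix(corpus, vocab)
    alpha = config.effective_alpha()
    eta = config.effective_eta()
    seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    gamma, lam = _vb_lda(X, M, alpha, eta, config.passes, rng)
    bound = _elbo(X, gamma, lam, alpha, eta)
    theta = gamma / gamma.sum(axis=1, keepdims=True)
    beta = lam / lam.sum(axis=1, keepdims=True)
    empty = X.sum(axis=1) == 0
    if empty.any():
        bad = [labels[i] for i in np.flatnonzero(empty)]
        warnings.warn(
            f"locus {corpus.locus_id!r}: documents {bad} have no tokens after "
            f"pruning; assigning uniform topic frequencies"
        )
        theta[empty] = 1.0 / M
    return TopicFit(
        locus_id=corpus.locus_id,
        labels=labels,
        theta=theta,
        beta=beta,
        bound=bound,
        vocabulary=vocab,
    )


def _top_words(beta_row: np.ndarray, top_n: int) -> np.ndarray:
    order = np.argsort(-beta_row, kind="stable")
    return order[: min(top_n, beta_row.size)]


def umass_coherence(fit: TopicFit, corpus: KmerCorpus, top_n: int = 10) -> list[float]:
    """Intrinsic topic coherence from document co-occurrence of each topic's
    top words (u_mass). For top words w_1..w_N in decreasing probability the
    topic score is the mean over pairs i < j of

        log[(D(w_i, w_j) + 1) / D(w_i)]

    where D counts documents of this locus containing the word(s). Near-zero
    scores mean the topic's top words ride together in documents.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    vocab = fit.vocabulary
    if vocab is None:
        raise ValueError("fit has no vocabulary attached")
    words = vocab.words
    doc_sets = [
        {w for w in counts if w in vocab.index} for counts in corpus.documents.values()
    ]

    def d_count(*ws: str) -> int:
        return sum(1 for s in doc_sets if all(w in s for w in ws))

    scores: list[float] = []
    for m in range(fit.num_topics):
        top = [words[j] for j in _top_words(fit.beta[m], top_n)]
        if len(top) < top_n:
            warnings.warn(
                f"topic {m}: only {len(top)} distinct words available "
                f"(requested {top_n})"
            )
        pair_scores = []
        for i in range(len(top)):
            for j in range(i + 1, len(top)):
                denom = d_count(top[i])
                if denom == 0:
                    continue  # word absent from every document; skip pair
                pair_scores.append(
                    np.log((d_count(top[i], top[j]) + 1.0) / denom)
                )
        scores.append(float(np.mean(pair_scores)) if pair_scores else 0.0)
    return scores


def select_num_topics(
    corpus: KmerCorpus,
    candidate_ms: Sequence[int],
    config: LdaConfig | None = None,
    top_n: int = 10,
) -> int:
    """Fit each candidate topic count and return the one with the highest
    mean u_mass coherence; ties break toward the smaller M. A single
    candidate is returned without fitting."""
    config = config or LdaConfig()
    candidates = sorted(set(candidate_ms))
    if not candidates:
        raise ValueError("need at least one candidate topic count")
    if len(candidates) == 1:
        return candidates[0]
    best_m, best_score = None, -np.inf
    for m in candidates:
        cfg = LdaConfig(
            num_topics=m,
            alpha=config.alpha,
            eta=config.eta,
            passes=config.passes,
            seed=config.seed,
            min_corpus_freq=config.min_corpus_freq,
            min_doc_freq=config.min_doc_freq,
        )
        fit = fit_lda(corpus, config=cfg)
        score = float(np.mean(umass_coherence(fit, corpus, top_n=top_n)))
        if score > best_score + 1e-12:
            best_m, best_score = m, score
    return int(best_m)
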