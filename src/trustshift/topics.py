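"""Topic modelling and topic-based corpus filtering.

A latent Dirichlet allocation model is fitted by collapsed Gibbs sampling:
token-topic assignments are resampled from their full conditional
p(z=k | ...) prop-to (n_dk + alpha) (n_kw + beta) / (n_k + V beta), and the
document-topic and topic-word distributions are estimated from counts
averaged over the post-burn-in sweeps, with Dirichlet smoothing.  Documents
are then retained when their posterior mass on an operator-selected set of
topics reaches a threshold (0.95 by default) — the mechanism used to strip
confounder topics (off-topic word clusters, non-English clusters) from a
keyword-scraped corpus.

The Gibbs sweep visits documents and tokens in fixed order with a single
seeded RNG, so fits are reproducible.  The inner sweep is numba-compiled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdaConfig:
    n_topics: int = 20
    alpha: float | None = None  # None -> 50 / n_topics
    beta: float = 0.01
    n_iterations: int = 1000
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if (self.alpha is not None and self.alpha <= 0) or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (self.n_iterations > self.burn_in >= 0):
            raise ValueError("require n_iterations > burn_in >= 0")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.n_topics


@dataclass
class TopicModel:
    topic_word: np.ndarray  # (K, V) rows sum to 1
    vocabulary: dict[str, int]
    doc_topic: np.ndarray  # (N, K) rows sum to 1
    assignments: np.ndarray  # final token-topic states (flat token order)
    term_counts: np.ndarray  # raw corpus frequency per vocab column
    config: LdaConfig

    @property
    def n_topics(self) -> int:
        return self.topic_word.shape[0]

    @property
    def index_to_term(self) -> list[str]:
        inv = [""] * len(self.vocabulary)
        for w, i in self.vocabulary.items():
            inv[i] = w
        return inv


@njit(cache=False)
def _gibbs_lda(w_arr, d_arr, n_docs, n_vocab, n_topics, alpha, beta,
               n_iterations, burn_in, seed):
    np.random.seed(seed)
    T = w_arr.size
    ndk = np.zeros((n_docs, n_topics), dtype=np.float64)
    nwk = np.zeros((n_vocab, n_topics), dtype=np.float64)
    nk = np.zeros(n_topics, dtype=np.float64)
    z_arr = np.empty(T, dtype=np.int64)
    for t in range(T):
        z = np.random.randint(0, n_topics)
        z_arr[t] = z
        ndk[d_arr[t], z] += 1.0
        nwk[w_arr[t], z] += 1.0
        nk[z] += 1.0
    ndk_sum = np.zeros((n_docs, n_topics), dtype=np.float64)
    nwk_sum = np.zeros((n_vocab, n_topics), dtype=np.float64)
    vbeta = n_vocab * beta
    p = np.empty(n_topics, dtype=np.float64)
    for it in range(n_iterations):
        for t in range(T):
            d = d_arr[t]
            w = w_arr[t]
            z = z_arr[t]
            ndk[d, z] -= 1.0
            nwk[w, z] -= 1.0
            nk[z] -= 1.0
            total = 0.0
            for k in range(n_topics):
                val = (ndk[d, k] + alpha) * (nwk[w, k] + beta) / (nk[k] + vbeta)
                p[k] = val
                total += val
            u = np.random.random() * total
            acc = 0.0
            z = n_topics - 1
            for k in range(n_topics):
                acc += p[k]
                if u <= acc:
                    z = k
                    break
            z_arr[t] = z
            ndk[d, z] += 1.0
            nwk[w, z] += 1.0
            nk[z] += 1.0
        if it >= burn_in:
            ndk_sum += ndk
            nwk_sum += nwk
    n_kept = n_iterations - burn_in
    return ndk_sum / n_kept, nwk_sum / n_kept, z_arr


def fit_lda(docs: Sequence[Sequence[str]], cfg: LdaConfig) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling; deterministic given cfg.seed."""
    vocab: dict[str, int] = {}
    term_counts: list[int] = []
    w_list: list[int] = []
    d_list: list[int] = []
    for d, doc in enumerate(docs):
        for tok in doc:
            idx = vocab.get(tok)
            if idx is None:
                idx = len(vocab)
                vocab[tok] = idx
                term_counts.append(0)
            term_counts[idx] += 1
            w_list.append(idx)
            d_list.append(d)
    if not w_list:
        raise ValueError("cannot fit LDA on an all-empty corpus")
    n_docs = len(docs)
    w_arr = np.asarray(w_list, dtype=np.int64)
    d_arr = np.asarray(d_list, dtype=np.int64)
    alpha = cfg.effective_alpha
    ndk_avg, nwk_avg, z_arr = _gibbs_lda(
        w_arr, d_arr, n_docs, len(vocab), cfg.n_topics, alpha, cfg.beta,
        cfg.n_iterations, cfg.burn_in, cfg.seed % (2**31),
    )
    doc_topic = ndk_avg + alpha
    doc_topic /= doc_topic.sum(axis=1, keepdims=True)
    topic_word = nwk_avg.T + cfg.beta
    topic_word /= topic_word.sum(axis=1, keepdims=True)
    return TopicModel(
        topic_word=topic_word,
        vocabulary=vocab,
        doc_topic=doc_topic,
        assignments=z_arr,
        term_counts=np.asarray(term_counts, dtype=np.int64),
        config=cfg,
    )


def score_documents(
    model: TopicModel,
    docs: Sequence[Sequence[str]] | None = None,
    n_iterations: int = 100,
    burn_in: int = 20,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-document topic probabilities, plus a zero-in-vocab flag vector.

    With ``docs=None`` the stored training ``doc_topic`` is returned (no
    document is flagged).  Held-out documents are folded in: their token
    assignments are Gibbs-sampled with the topic-word distribution fixed and
    the post-burn-in counts averaged.  A document with no in-vocabulary
    tokens gets a uniform row and is flagged.
    """
    if docs is None:
        return model.doc_topic, np.zeros(model.doc_topic.shape[0], dtype=bool)
    K = model.n_topics
    alpha = model.config.effective_alpha
    rng = np.random.default_rng(model.config.seed + 101 if seed is None else seed)
    out = np.empty((len(docs), K))
    flags = np.zeros(len(docs), dtype=bool)
    phi = model.topic_word  # (K, V)
    for i, doc in enumerate(docs):
        ids = np.array([model.vocabulary[t] for t in doc if t in model.vocabulary],
                       dtype=np.int64)
        if ids.size == 0:
            out[i] = 1.0 / K
            flags[i] = True
            continue
        z = rng.integers(K, size=ids.size)
        ndk = np.bincount(z, minlength=K).astype(np.float64)
        ndk_sum = np.zeros(K)
        for it in range(n_iterations):
            for t in range(ids.size):
                ndk[z[t]] -= 1.0
                p = (ndk + alpha) * phi[:, ids[t]]
                cp = np.cumsum(p)
                z[t] = int(np.searchsorted(cp, rng.random() * cp[-1]))
                ndk[z[t]] += 1.0
            if it >= burn_in:
                ndk_sum += ndk
        theta = ndk_sum / (n_iterations - burn_in) + alpha
        out[i] = theta / theta.sum()
    return out, flags


def filter_by_topics(
    records: Sequence,
    scores: np.ndarray,
    selected_topics: Sequence[int],
    threshold: float = 0.95,
):
    """Keep records whose summed probability over selected topics >= threshold."""
    selected = sorted(set(int(k) for k in selected_topics))
    if not selected:
        raise ValueError("selected_topics must be nonempty")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if max(selected) >= scores.shape[1] or min(selected) < 0:
        raise ValueError("selected topic index out of range")
    mass = scores[:, selected].sum(axis=1)
    mask = mass >= threshold
    survivors = [rec for rec, keep in zip(records, mask) if keep]
    return survivors, mask


def top_terms(model: TopicModel, topic: int, n: int = 10) -> list[tuple[str, float, int]]:
    """Top-``n`` (term, weight, corpus count), weight desc then lexicographic."""
    if not (0 <= topic < model.n_topics):
        raise ValueError(f"topic {topic} out of range")
    terms = model.index_to_term
    order = sorted(
        range(len(terms)), key=lambda i: (-model.topic_word[topic, i], terms[i])
    )
    return [
        (terms[i], float(model.topic_word[topic, i]), int(model.term_counts[i]))
        for i in order[:n]
    ]


def salient_topics(
    model: TopicModel,
    salient_terms: Sequence[str],
    n_top: int = 15,
    min_hits: int = 2,
) -> list[int]:
    """Operator aid: topics whose top terms contain >= min_hits salient terms.

    Mirrors how an analyst inspects topic term lists to decide which topics
    carry the subject of interest; the result is still an explicit input to
    :func:`filter_by_topics`.
    """
    wanted = set(salient_terms)
    chosen = []
    for k in range(model.n_topics):
        hits = sum(1 for term, _, _ in top_terms(model, k, n_top) if term in wanted)
        if hits >= min_hits:
            chosen.append(k)
    return chosen


def held_out_perplexity(
    model: TopicModel, docs: Sequence[Sequence[str]], **score_kwargs
) -> float:
    """exp(-mean log p(token)) under fold-in document mixtures."""
    theta, _ = score_documents(model, docs, **score_kwargs)
    log_lik = 0.0
    n_tokens = 0
    for i, doc in enumerate(docs):
        for tok in doc:
            j = model.vocabulary.get(tok)
            if j is None:
                continue
            log_lik += np.log(theta[i] @ model.topic_word[:, j])
            n_tokens += 1
    if n_tokens == 0:
        raise ValueError("no in-vocabulary tokens in held-out docs")
    return float(np.exp(-log_lik / n_tokens))


def save_model(model: TopicModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    terms = model.index_to_term
    with (d / "vocabulary.tsv").open("w") as fh:
        for i, term in enumerate(terms):
            fh.write(f"{term}\t{i}\t{int(model.term_counts[i])}\n")
    np.savetxt(d / "topic_word.csv", model.topic_word, delimiter=",")
    np.savetxt(d / "doc_topic.csv", model.doc_topic, delimiter=",")
    with (d / "config.json").open("w") as fh:
        json.dump(asdict(model.config), fh, indent=1)


def load_model(directory: str | Path) -> TopicModel:
    d = Path(directory)
    vocab: dict[str, int] = {}
    counts: list[int] = []
    with (d / "vocabulary.tsv").open() as fh:
        for line in fh:
            term, idx, cnt = line.rstrip("\n").split("\t")
            vocab[term] = int(idx)
            counts.append(int(cnt))
    topic_word = np.loadtxt(d / "topic_word.csv", delimiter=",", ndmin=2)
    doc_topic = np.loadtxt(d / "doc_topic.csv", delimiter=",", ndmin=2)
    with (d / "config.json").open() as fh:
        cfg = LdaConfig(**json.load(fh))
    return TopicModel(
        topic_word=topic_word,
        vocabulary=vocab,
        doc_topic=doc_topic,
        assignments=np.empty(0, dtype=np.int64),
        term_counts=np.asarray(counts, dtype=np.int64),
        config=cfg,
    )
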