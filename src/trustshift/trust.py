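"""Trust-dimension analysis of word embeddings.

Skip-gram-with-negative-sampling (SGNS) embeddings are trained separately on
the pre- and post-period corpora.  A latent *trust dimension* is extracted
from paired antonym anchors ("trust"/"mistrust", "reliable"/"unreliable",
...): each in-vocabulary pair contributes the unit-normalised difference of
its word vectors, and the axis is the unit-normalised mean of those pair
vectors.  A target term's trust connotation in a period is the cosine
similarity of its vector to that period's axis; terms missing from a
period's vocabulary are reported as out-of-vocabulary rather than given a
default score.

Training is single-threaded and fully deterministic given the seed.  Target
vectors are the input (centre-word) matrix, the standard choice for semantic
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE_ANCHORS = (
    "trust", "trustworthy", "faith", "reliable", "confidence", "certainty",
    "conviction",
)
NEGATIVE_ANCHORS = (
    "mistrust", "untrustworthy", "distrust", "unreliable", "skepticism",
    "uncertainty", "doubt",
)

CLINICIAN_TERMS = (
    "doctor", "provider", "physician", "nurse", "ob", "gyn", "obgyn", "pcp",
    "healthcare",
)
HEALTH_INFORMATION_TERMS = (
    "app", "information", "periodtracking", "tracking", "phi", "hipaa", "data",
)


@dataclass(frozen=True)
class AnchorSet:
    """Paired positive/negative anchor words defining the semantic axis."""

    positive: tuple[str, ...] = POSITIVE_ANCHORS
    negative: tuple[str, ...] = NEGATIVE_ANCHORS

    def __post_init__(self) -> None:
        if len(self.positive) != len(self.negative):
            raise ValueError("anchor lists must pair up: unequal lengths")
        if set(self.positive) & set(self.negative):
            raise ValueError("a word appears in both anchor lists")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.positive, self.negative))

    def swapped(self) -> "AnchorSet":
        return AnchorSet(positive=self.negative, negative=self.positive)


@dataclass(frozen=True)
class TermSet:
    """Target terms projected onto the axis, grouped for reporting."""

    clinician: tuple[str, ...] = CLINICIAN_TERMS
    health_information: tuple[str, ...] = HEALTH_INFORMATION_TERMS

    def __post_init__(self) -> None:
        for group in (self.clinician, self.health_information):
            if not group:
                raise ValueError("term groups must be nonempty")
            if any(t != t.lower() for t in group):
                raise ValueError("terms must be lowercase")

    @property
    def groups(self) -> dict[str, tuple[str, ...]]:
        return {
            "clinician": self.clinician,
            "health_information": self.health_information,
        }


@dataclass(frozen=True)
class SgnsConfig:
    dim: int = 100
    window: int = 5
    negative: int = 5
    epochs: int = 5
    min_count: int = 5
    subsample: float = 1e-3
    lr: float = 0.025
    lr_min: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negative < 0:
            raise ValueError("invalid SGNS configuration")
        if self.epochs < 1 or self.min_count < 1:
            raise ValueError("invalid SGNS configuration")


@dataclass
class EmbeddingModel:
    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim) input/centre vectors
    context_vectors: np.ndarray  # (V, dim) output vectors
    counts: np.ndarray  # corpus frequency per vocab word
    config: SgnsConfig
    epoch_losses: list[float] = field(default_factory=list)

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocab[word]]

    @property
    def index_to_word(self) -> list[str]:
        inv = [""] * len(self.vocab)
        for w, i in self.vocab.items():
            inv[i] = w
        return inv

    def save_word2vec(self, path) -> None:
        """Plain-text word2vec format: header ``V d``, one word per line."""
        words = self.index_to_word
        with open(path, "w") as fh:
            fh.write(f"{len(words)} {self.vectors.shape[1]}\n")
            for i, w in enumerate(words):
                vec = " ".join(f"{x:.6f}" for x in self.vectors[i])
                fh.write(f"{w} {vec}\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_sgns(docs: Sequence[Sequence[str]], cfg: SgnsConfig) -> EmbeddingModel:
    """Train SGNS embeddings on tokenized documents.

    For each (centre, context) pair inside a dynamically shrunk window the
    objective log s(u_c . v_w) + sum_k log s(-u_nk . v_w) is maximised by SGD
    with a linearly decaying learning rate; negatives are drawn from the
    unigram^0.75 distribution.  Frequent words are down-sampled with the
    standard sqrt(threshold/frequency) keep rule.  ``epoch_losses`` records
    the objective on a fixed probe batch before training (index 0) and after
    every epoch, as an optimisation sanity trace.
    """
    rng = np.random.default_rng(cfg.seed)
    freq: dict[str, int] = {}
    total_raw = 0
    for doc in docs:
        for tok in doc:
            freq[tok] = freq.get(tok, 0) + 1
            total_raw += 1
    if total_raw == 0:
        raise ValueError("cannot train embeddings on an empty corpus")
    # deterministic vocabulary order: frequency desc, then lexicographic
    kept = sorted(
        (w for w, c in freq.items() if c >= cfg.min_count),
        key=lambda w: (-freq[w], w),
    )
    if not kept:
        raise ValueError("no word reaches min_count; corpus too small")
    vocab = {w: i for i, w in enumerate(kept)}
    counts = np.array([freq[w] for w in kept], dtype=np.int64)
    V, d = len(kept), cfg.dim
    total = int(counts.sum())

    # subsampling keep-probabilities
    if cfg.subsample > 0:
        f = counts / total
        keep_prob = np.minimum(1.0, np.sqrt(cfg.subsample / f))
    else:
        keep_prob = np.ones(V)

    # negative-sampling table: unigram^0.75
    noise = counts.astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    W = (rng.random((V, d)) - 0.5) / d
    C = np.zeros((V, d))

    encoded_docs = [
        np.array([vocab[t] for t in doc if t in vocab], dtype=np.int64)
        for doc in docs
    ]
    encoded_docs = [ids for ids in encoded_docs if ids.size > 0]

    # fixed probe batch for the loss trace
    probe_centers: list[int] = []
    probe_contexts: list[int] = []
    for ids in encoded_docs[:200]:
        for i in range(len(ids) - 1):
            probe_centers.append(ids[i])
            probe_contexts.append(ids[i + 1])
            if len(probe_centers) >= 512:
                break
        if len(probe_centers) >= 512:
            break
    pc = np.array(probe_centers, dtype=np.int64)
    px = np.array(probe_contexts, dtype=np.int64)
    pn = np.searchsorted(noise_cdf, rng.random((pc.size, max(cfg.negative, 1))))

    def probe_loss() -> float:
        if pc.size == 0:
            return 0.0
        pos = np.einsum("ij,ij->i", W[pc], C[px])
        neg = np.einsum("ij,ikj->ik", W[pc], C[pn])
        return float(
            -(np.log(_sigmoid(pos)).mean() + np.log(_sigmoid(-neg)).sum(axis=1).mean())
        )

    approx_centers = max(int(sum(ids.size for ids in encoded_docs)) * cfg.epochs, 1)
    step = 0
    losses: list[float] = [probe_loss()]  # index 0 = before any training
    for _ in range(cfg.epochs):
        for ids in encoded_docs:
            if cfg.subsample > 0:
                mask = rng.random(ids.size) < keep_prob[ids]
                sent = ids[mask]
            else:
                sent = ids
            n = sent.size
            if n < 2:
                step += n
                continue
            spans = rng.integers(1, cfg.window + 1, size=n)
            for i in range(n):
                w = sent[i]
                b = spans[i]
                ctx = np.concatenate((sent[max(0, i - b):i], sent[i + 1:i + 1 + b]))
                step += 1
                if ctx.size == 0:
                    continue
                lr = max(cfg.lr * (1.0 - step / approx_centers), cfg.lr_min)
                negs = np.searchsorted(
                    noise_cdf, rng.random(ctx.size * cfg.negative)
                )
                rows = np.concatenate((ctx, negs))
                labels = np.zeros(rows.size)
                labels[: ctx.size] = 1.0
                v = W[w]
                U = C[rows]
                g = lr * (labels - _sigmoid(U @ v))
                W[w] = v + g @ U
                np.add.at(C, rows, g[:, None] * v)
        losses.append(probe_loss())

    return EmbeddingModel(
        vocab=vocab,
        vectors=W,
        context_vectors=C,
        counts=counts,
        config=cfg,
        epoch_losses=losses,
    )


def build_axis(model: EmbeddingModel, anchors: AnchorSet) -> np.ndarray:
    """Unit trust axis: mean of unit-normalised (positive - negative) pairs.

    Pairs with an out-of-vocabulary member are skipped (and logged); all
    pairs missing is an error, as is a zero-norm mean.
    """
    pair_vecs = []
    skipped = []
    for pos, neg in anchors.pairs:
        if pos in model and neg in model:
            diff = model.vector(pos) - model.vector(neg)
            norm = np.linalg.norm(diff)
            if norm == 0:
                raise ValueError(f"anchor pair ({pos}, {neg}) has zero difference")
            pair_vecs.append(diff / norm)
        else:
            skipped.append((pos, neg))
    if skipped:
        logger.info("build_axis: skipped OOV anchor pairs %s", skipped)
    if not pair_vecs:
        raise ValueError("no anchor pair has both words in vocabulary")
    axis = np.mean(pair_vecs, axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("anchor pairs cancel out: zero-norm axis")
    return axis / norm


def project_term(
    model: EmbeddingModel, axis: np.ndarray, term: str
) -> float | None:
    """Cosine similarity of ``term``'s vector to the axis; None if OOV."""
    if term not in model:
        return None
    v = model.vector(term)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"term {term!r} has a zero-norm vector")
    return float(v @ axis / (norm * np.linalg.norm(axis)))


@dataclass
class TrustAxisReport:
    """Per-term, per-period cosine scores against the trust dimension."""

    rows: list[dict]  # term, group, period, score (float|None), oov (bool)

    def score(self, term: str, period: str) -> float | None:
        for r in self.rows:
            if r["term"] == term and r["period"] == period:
                return r["score"]
        raise KeyError((term, period))

    def delta(self, term: str) -> float | None:
        pre, post = self.score(term, "pre"), self.score(term, "post")
        if pre is None or post is None:
            return None
        return post - pre

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "group", "period", "score", "oov"])
            for r in self.rows:
                w.writerow(
                    [
                        r["term"],
                        r["group"],
                        r["period"],
                        "" if r["score"] is None else f"{r['score']:.6f}",
                        int(r["oov"]),
                    ]
                )


def compare_periods(
    pre_model: EmbeddingModel,
    post_model: EmbeddingModel,
    anchors: AnchorSet,
    terms: TermSet,
) -> TrustAxisReport:
    """Project every target term onto each period's own trust axis.

    Axes are built independently within each period's embedding space, so no
    cross-model alignment is needed; a term missing from one period is
    reported OOV there and still scored in the other (terms can be absent
    from one period's data entirely).
    """
    axes = {
        "pre": build_axis(pre_model, anchors),
        "post": build_axis(post_model, anchors),
    }
    models = {"pre": pre_model, "post": post_model}
    rows = []
    for group, group_terms in terms.groups.items():
        for term in group_terms:
            for period in ("pre", "post"):
                score = project_term(models[period], axes[period], term)
                rows.append(
                    {
                        "term": term,
                        "group": group,
                        "period": period,
                        "score": score,
                        "oov": score is None,
                    }
                )
    return TrustAxisReport(rows=rows)
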