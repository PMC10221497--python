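"""Seeded synthetic tweet corpora with planted ground truth.

Every downstream stage of the analysis (deduplication, topic filtering,
sentiment aggregation, the counterfactual, the trust axis, term volumes) is
exercised against corpora generated here, where the truth is known by
construction:

* daily unique-user counts are Poisson with a multiplicative step at the
  period boundary (the engagement signal);
* each tweet draws its words from one of several planted topic vocabularies
  (including at least one confounder topic) so topic recovery is testable;
* each tweet carries exactly one token from one of three disjoint sentiment
  marker lexicons, so the default lexicon classifier recovers the planted
  label exactly;
* trust-plant directives make chosen target terms co-occur with the positive
  or negative trust anchors, switchable between periods, so the semantic-axis
  projection has a recoverable sign;
* a configurable fraction of tweets is emitted twice verbatim (distinct ids)
  to exercise deduplication.

One RNG stream, seeded once; all sampling draws from it in a fixed order, so
identical (spec, seed) pairs produce byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import TweetRecord
from .sentiment import NEGATIVE_MARKERS, NEUTRAL_MARKERS, POSITIVE_MARKERS
from .trust import AnchorSet

SENTIMENT_MARKERS = {
    "negative": NEGATIVE_MARKERS,
    "neutral": NEUTRAL_MARKERS,
    "positive": POSITIVE_MARKERS,
}

#: Planted topic vocabularies: policy/legality, health privacy, and a
#: celebrity confounder (the kind of off-topic cluster topic filtering must
#: remove).  "pcp" and "periodtracking" are deliberately absent so they can
#: enter post-period corpora only through trust plants.
DEFAULT_TOPIC_VOCAB: tuple[tuple[str, ...], ...] = (
    (
        "roe", "wade", "abortion", "state", "law", "constitution", "court",
        "decision", "ruling", "ban", "legal", "rights",
    ),
    (
        "privacy", "right", "woman", "please", "health", "doctor", "data",
        "app", "hipaa", "phi", "tracking", "information", "nurse", "provider",
        "physician", "ob", "gyn", "obgyn", "healthcare", "period",
    ),
    (
        "jackson", "michael", "music", "album", "song", "dance", "concert",
        "tour", "fan", "pop", "stage", "record",
    ),
)

#: Short connective filler words: they make texts effectively unique (so a
#: duplicate_rate of 0 really means no duplicate texts) and are dropped by
#: the LDA/TF-IDF token filter.
FILLER_WORDS: tuple[str, ...] = (
    "a", "an", "as", "at", "be", "by", "do", "go", "he", "if", "in", "is",
    "it", "me", "my", "no", "of", "on", "or", "so", "to", "up", "us", "we",
    "and", "but", "for", "her", "him", "his", "its", "nor", "not", "now",
    "our", "out", "she", "the", "too", "was", "who", "why", "yet", "you",
    "all", "any", "are", "can", "did", "had", "has", "how", "may", "one",
    "own", "per", "say", "see", "two", "via", "way", "will", "with",
)


class SpecValidationError(ValueError):
    """A CorpusSpec field violates its invariant; the message names it."""


@dataclass(frozen=True)
class TrustPlant:
    """Directive: make ``term`` co-occur with one anchor pole in one period."""

    term: str
    period: str  # "pre" | "post"
    polarity: str  # "positive" | "negative"
    insert_rate: float = 0.35  # probability a tweet of that period carries the term
    excess_rate: float = 2.5  # mean anchor insertions per target occurrence
    window: int = 2

    def __post_init__(self) -> None:
        if self.period not in ("pre", "post"):
            raise SpecValidationError(f"trust_plants.period invalid: {self.period!r}")
        if self.polarity not in ("positive", "negative"):
            raise SpecValidationError(
                f"trust_plants.polarity invalid: {self.polarity!r}"
            )
        if self.excess_rate < 0 or not (0 <= self.insert_rate <= 1):
            raise SpecValidationError("trust_plants rates out of range")


#: Default plants mirror the qualitative pattern reported for real data:
#: clinician/app terms positively trust-associated pre and negatively post;
#: "pcp" and "periodtracking" appearing only post (OOV pre).
DEFAULT_TRUST_PLANTS: tuple[TrustPlant, ...] = (
    TrustPlant("doctor", "pre", "positive"),
    TrustPlant("doctor", "post", "negative"),
    TrustPlant("app", "pre", "positive"),
    TrustPlant("app", "post", "negative"),
    TrustPlant("hipaa", "pre", "negative"),
    TrustPlant("hipaa", "post", "negative"),
    TrustPlant("pcp", "post", "negative"),
    TrustPlant("periodtracking", "post", "negative"),
)


def _validate_probs(name: str, probs: Sequence[float], n: int) -> None:
    if len(probs) != n:
        raise SpecValidationError(f"{name} must have length {n}")
    if any(p < 0 for p in probs):
        raise SpecValidationError(f"{name} has negative entries")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise SpecValidationError(f"{name} must sum to 1 within 1e-9")


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for corpus generation.

    Defaults are the real study's conditions: pre-period 2020-01-01 to
    2022-05-01, post-period 2022-05-02 to 2022-10-17; a post-period
    engagement step of x6.77 (matching a +577% relative effect); sentiment
    mixes whose encoded means are 0.44 pre and 0.35 post.
    """

    seed: int = 0
    pre_start: date = date(2020, 1, 1)
    pre_end: date = date(2022, 5, 1)
    post_start: date = date(2022, 5, 2)
    post_end: date = date(2022, 10, 17)
    base_daily_users: float = 50.0
    engagement_multiplier: float = 6.77
    tweets_per_user: float = 1.2
    topic_vocab: tuple[tuple[str, ...], ...] = DEFAULT_TOPIC_VOCAB
    topic_mix: dict = field(
        default_factory=lambda: {
            "pre": (0.45, 0.35, 0.20),
            "post": (0.50, 0.40, 0.10),
        }
    )
    sentiment_probs: dict = field(
        default_factory=lambda: {
            "pre": (0.32, 0.48, 0.20),  # encoded mean 0.44
            "post": (0.45, 0.40, 0.15),  # encoded mean 0.35
        }
    )
    trust_plants: tuple[TrustPlant, ...] = DEFAULT_TRUST_PLANTS
    duplicate_rate: float = 0.10
    min_tokens: int = 7
    max_tokens: int = 12
    n_filler: int = 3
    anchor_background_rate: float = 0.6
    anchors: AnchorSet = field(default_factory=AnchorSet)

    def __post_init__(self) -> None:
        if not (self.pre_start <= self.pre_end < self.post_start <= self.post_end):
            raise SpecValidationError(
                "dates must satisfy pre_start <= pre_end < post_start <= post_end"
            )
        if self.base_daily_users <= 0:
            raise SpecValidationError("base_daily_users must be positive")
        if self.engagement_multiplier <= 0:
            raise SpecValidationError("engagement_multiplier must be positive")
        if self.tweets_per_user <= 0:
            raise SpecValidationError("tweets_per_user must be positive")
        if not (0 <= self.duplicate_rate <= 1):
            raise SpecValidationError("duplicate_rate must be in [0, 1]")
        if not self.topic_vocab or any(len(v) == 0 for v in self.topic_vocab):
            raise SpecValidationError("topic_vocab lists must be nonempty")
        for period in ("pre", "post"):
            _validate_probs(
                f"topic_mix[{period}]", self.topic_mix[period], len(self.topic_vocab)
            )
            _validate_probs(f"sentiment_probs[{period}]", self.sentiment_probs[period], 3)
        if not (self.min_tokens >= 1 and self.max_tokens >= self.min_tokens):
            raise SpecValidationError("token length bounds invalid")

    def days(self, period: str) -> list[date]:
        start, end = (
            (self.pre_start, self.pre_end)
            if period == "pre"
            else (self.post_start, self.post_end)
        )
        n = (end - start).days + 1
        return [start + timedelta(days=i) for i in range(n)]


@dataclass
class GroundTruth:
    """Planted labels keyed by tweet id (duplicates share their original's)."""

    daily_user_counts: dict  # ISO date -> int
    sentiment: dict  # tweet id -> label
    topic: dict  # tweet id -> topic index
    trust_polarity: dict  # "term|period" -> polarity
    n_originals: int = 0
    n_duplicates: int = 0

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with Path(path).open() as fh:
            obj = json.load(fh)
        obj["topic"] = {k: int(v) for k, v in obj["topic"].items()}
        return cls(**obj)


def plant_trust_cooccurrence(
    tokens: Sequence[str],
    directive: TrustPlant,
    anchors: AnchorSet | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Insert anchor words of the directed polarity near the target term.

    For each occurrence of ``directive.term``, a Poisson(``excess_rate``)
    number of anchor words from the matching pole is inserted at offsets
    within ``directive.window`` of the occurrence.  With ``excess_rate`` 0
    the token sequence is returned unchanged.
    """
    anchors = anchors if anchors is not None else AnchorSet()
    rng = rng if rng is not None else np.random.default_rng(0)
    if directive.polarity == "positive":
        pool = anchors.positive
    elif directive.polarity == "negative":
        pool = anchors.negative
    else:  # defensive; TrustPlant already validates
        raise SpecValidationError(f"unknown polarity {directive.polarity!r}")
    tokens = list(tokens)
    if not tokens:
        return []
    insertions: list[tuple[int, str]] = []
    for idx, tok in enumerate(tokens):
        if tok != directive.term:
            continue
        n_ins = rng.poisson(directive.excess_rate)
        for _ in range(n_ins):
            offset = int(rng.integers(-directive.window, directive.window + 1))
            pos = int(np.clip(idx + offset, 0, len(tokens)))
            word = pool[int(rng.integers(len(pool)))]
            insertions.append((pos, word))
    for pos, word in sorted(insertions, key=lambda x: x[0], reverse=True):
        tokens.insert(pos, word)
    return tokens


def _make_text(
    spec: CorpusSpec,
    period: str,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """One tweet's text plus its planted (sentiment label, topic index)."""
    k = int(rng.choice(len(spec.topic_vocab), p=spec.topic_mix[period]))
    vocab = spec.topic_vocab[k]
    length = int(rng.integers(spec.min_tokens, spec.max_tokens + 1))
    tokens = [vocab[int(i)] for i in rng.integers(len(vocab), size=length)]

    label = ("negative", "neutral", "positive")[
        int(rng.choice(3, p=spec.sentiment_probs[period]))
    ]
    marker = SENTIMENT_MARKERS[label][int(rng.integers(3))]
    tokens.insert(int(rng.integers(len(tokens) + 1)), marker)

    # background anchor mood: same-pole anchors co-occur, giving the axis
    # its geometry independently of the planted targets
    if rng.random() < spec.anchor_background_rate:
        pole = spec.anchors.positive if rng.random() < 0.5 else spec.anchors.negative
        for _ in range(1 + rng.poisson(0.7)):
            w = pole[int(rng.integers(len(pole)))]
            tokens.insert(int(rng.integers(len(tokens) + 1)), w)

    # trust plants active in this period
    for plant in spec.trust_plants:
        if plant.period != period:
            continue
        if rng.random() < plant.insert_rate:
            tokens.insert(int(rng.integers(len(tokens) + 1)), plant.term)
            tokens = plant_trust_cooccurrence(tokens, plant, spec.anchors, rng)

    # connective fillers -> texts are effectively collision-free
    for _ in range(spec.n_filler):
        w = FILLER_WORDS[int(rng.integers(len(FILLER_WORDS)))]
        tokens.insert(int(rng.integers(len(tokens) + 1)), w)

    return " ".join(tokens), label, k


def generate_corpus(spec: CorpusSpec) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate the corpus and its ground truth, deterministically.

    Daily active-user counts are Poisson(base_daily_users) in the pre period
    and Poisson(base_daily_users * engagement_multiplier) post; each active
    user posts 1 + Poisson(tweets_per_user - 1) tweets that day.  Duplicate
    emissions (verbatim text, fresh id, same labels) immediately follow their
    original with probability ``duplicate_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[TweetRecord] = []
    gt = GroundTruth(
        daily_user_counts={},
        sentiment={},
        topic={},
        trust_polarity={
            f"{p.term}|{p.period}": p.polarity for p in spec.trust_plants
        },
    )
    counter = 0
    for period in ("pre", "post"):
        intensity = spec.base_daily_users * (
            spec.engagement_multiplier if period == "post" else 1.0
        )
        mean_extra = max(spec.tweets_per_user - 1.0, 0.0)
        for day_idx, day in enumerate(spec.days(period)):
            n_users = int(rng.poisson(intensity))
            gt.daily_user_counts[day.isoformat()] = n_users
            for u in range(n_users):
                user_id = f"{period[0]}{day.isoformat()}u{u:05d}"
                n_posts = 1 + int(rng.poisson(mean_extra))
                for _ in range(n_posts):
                    text, label, topic_k = _make_text(spec, period, rng)
                    second = int(rng.integers(86400))
                    ts = datetime.combine(day, datetime.min.time()) + timedelta(
                        seconds=second
                    )
                    tid = f"t{counter:08d}"
                    counter += 1
                    rec = TweetRecord(id=tid, timestamp=ts, user_id=user_id, text=text)
                    records.append(rec)
                    gt.sentiment[tid] = label
                    gt.topic[tid] = topic_k
                    gt.n_originals += 1
                    if spec.duplicate_rate > 0 and rng.random() < spec.duplicate_rate:
                        did = tid + "d"
                        records.append(
                            TweetRecord(
                                id=did, timestamp=ts, user_id=user_id, text=text
                            )
                        )
                        gt.sentiment[did] = label
                        gt.topic[did] = topic_k
                        gt.n_duplicates += 1
    return records, gt


def write_corpus_jsonl(records: Sequence[TweetRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "id": rec.id,
                        "timestamp": rec.timestamp.isoformat(),
                        "user_id": rec.user_id,
                        "text": rec.text,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def simulate_level_series(
    seed: int | np.random.Generator,
    n_pre: int = 300,
    n_post: int = 150,
    level0: float = 100.0,
    sigma_level: float = 1.0,
    sigma_obs: float = 5.0,
    post_multiplier: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Local-level series with an optional multiplicative post-period step.

    The latent level is a Gaussian random walk and observations add white
    noise; the post segment is the *null* continuation of the same process
    scaled by ``post_multiplier`` (1.0 = no intervention).  The default
    signal-to-noise (sigma_level/sigma_obs = 0.2, level ~ 100) emulates a
    daily-active-users series with slow drift and dominant day-to-day noise.
    Returns (pre observations, observed post observations).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_pre + n_post
    level = level0 + np.cumsum(rng.normal(0.0, sigma_level, n))
    y = level + rng.normal(0.0, sigma_obs, n)
    return y[:n_pre], y[n_pre:] * post_multiplier


def demo_spec(seed: int = 0) -> CorpusSpec:
    """Desk-scale corpus: 90 pre days + 45 post days, small user intensity.

    Same structure as the full study conditions, sized so the complete
    pipeline (LDA, two counterfactual fits, two embedding models) runs in a
    couple of minutes on one CPU.
    """
    return CorpusSpec(
        seed=seed,
        pre_start=date(2022, 2, 1),
        pre_end=date(2022, 5, 1),
        post_start=date(2022, 5, 2),
        post_end=date(2022, 6, 15),
        base_daily_users=12.0,
        engagement_multiplier=3.0,
        tweets_per_user=1.2,
        duplicate_rate=0.10,
    )
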