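"""Per-tweet sentiment classification and daily aggregation.

Sentiment enters the analysis as an ordinal encoding of a three-class label:
negative -> 0, neutral -> 0.5, positive -> 1.0.  The classifier itself is a
plug-in satisfying a ``text -> 3 probabilities`` contract (the ordering is
(negative, neutral, positive)); the shipped default is a marker-lexicon
classifier that is exact on synthetic corpora carrying dedicated sentiment
marker tokens.  Daily series are built on a gap-free calendar grid:
engagement (distinct users per day) fills empty days with 0, sentiment fills
them by linear interpolation, because the counterfactual model downstream
requires a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ingest import TweetRecord, tokenize

LABELS = ("negative", "neutral", "positive")
ENCODING = {"negative": 0.0, "neutral": 0.5, "positive": 1.0}

#: Disjoint marker-token sets planted by the synthetic corpus generator.
#: Dedicated out-of-language tokens so lexicon classification is exact.
NEGATIVE_MARKERS = ("gravemark", "diremark", "bleakmark")
NEUTRAL_MARKERS = ("plainmark", "evenmark", "flatmark")
POSITIVE_MARKERS = ("brightmark", "gladmark", "upliftmark")

#: Argmax ties break toward neutral, then negative (index order below).
_TIE_ORDER = (1, 0, 2)


class ClassifierContractError(ValueError):
    """The plug-in classifier returned something other than 3 probabilities."""


@dataclass(frozen=True)
class SentimentResult:
    label: str
    probabilities: tuple[float, float, float]  # (negative, neutral, positive)
    encoded: float


class LexiconClassifier:
    """Default classifier: count marker/lexicon hits per polarity.

    Probabilities put mass ``1 - 2*eps`` on the winning class.  Ties
    (including no hits at all) resolve to neutral.
    """

    def __init__(
        self,
        negative_words: Sequence[str] = NEGATIVE_MARKERS,
        neutral_words: Sequence[str] = NEUTRAL_MARKERS,
        positive_words: Sequence[str] = POSITIVE_MARKERS,
        eps: float = 0.05,
    ) -> None:
        self.lexicons = (set(negative_words), set(neutral_words), set(positive_words))
        self.eps = eps

    def __call__(self, text: str) -> tuple[float, float, float]:
        tokens = tokenize(text)
        counts = [sum(t in lex for t in tokens) for lex in self.lexicons]
        best = max(counts)
        winners = [i for i, c in enumerate(counts) if c == best]
        winner = winners[0] if len(winners) == 1 else next(
            i for i in _TIE_ORDER if i in winners
        )
        probs = [self.eps, self.eps, self.eps]
        probs[winner] = 1.0 - 2 * self.eps
        return tuple(probs)  # type: ignore[return-value]


def classify(
    tweet: TweetRecord | str,
    classifier: Callable[[str], Sequence[float]],
) -> SentimentResult:
    """Run the plug-in classifier and encode the argmax label ordinally.

    Ties break toward neutral, then negative.
    """
    text = tweet.text if isinstance(tweet, TweetRecord) else tweet
    raw = classifier(text)
    probs = np.asarray(raw, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ClassifierContractError(
            f"classifier must return 3 nonnegative probabilities summing to 1, got {raw!r}"
        )
    best = probs.max()
    idx = next(i for i in _TIE_ORDER if probs[i] >= best - 1e-12)
    label = LABELS[idx]
    return SentimentResult(
        label=label,
        probabilities=tuple(float(p) for p in probs),
        encoded=ENCODING[label],
    )


def classify_records(
    records: Sequence[TweetRecord],
    classifier: Callable[[str], Sequence[float]] | None = None,
) -> list[SentimentResult]:
    clf = classifier if classifier is not None else LexiconClassifier()
    return [classify(rec, clf) for rec in records]


@dataclass
class DailySeries:
    """A gap-free, date-indexed daily series with a pre/post boundary.

    ``values`` has a daily DatetimeIndex; ``boundary`` is the last pre-period
    date (dates after it are post-period).
    """

    values: pd.Series
    boundary: date

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("DailySeries must be on a gap-free daily grid")

    @property
    def dates(self) -> list[date]:
        return [ts.date() for ts in self.values.index]

    def pre(self) -> pd.Series:
        return self.values[self.values.index.date <= self.boundary]

    def post(self) -> pd.Series:
        return self.values[self.values.index.date > self.boundary]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "date": [d.isoformat() for d in self.dates],
                "value": self.values.to_numpy(),
                "period": ["pre" if d <= self.boundary else "post" for d in self.dates],
            }
        )
        df.to_csv(path, index=False)


def _date_index(records: Sequence[TweetRecord]) -> pd.DatetimeIndex:
    dates = [rec.date for rec in records]
    return pd.date_range(min(dates), max(dates), freq="D")


def daily_sentiment(
    records: Sequence[TweetRecord],
    results: Sequence[SentimentResult],
    boundary: date,
) -> DailySeries:
    """Mean encoded sentiment per calendar day.

    Days with no tweets are interpolated linearly between neighbouring
    observed days (ends are padded with the nearest observation) so the
    series stays on a regular grid in [0, 1].
    """
    if not records:
        raise ValueError("daily_sentiment requires at least one record")
    if len(records) != len(results):
        raise ValueError("records and results must align")
    s = pd.Series(
        [r.encoded for r in results],
        index=pd.to_datetime([rec.date for rec in records]),
    )
    daily = s.groupby(level=0).mean()
    full = daily.reindex(_date_index(records))
    full = full.interpolate(method="linear", limit_direction="both")
    return DailySeries(values=full, boundary=boundary)


def daily_engagement(
    records: Sequence[TweetRecord], boundary: date
) -> DailySeries:
    """Distinct users per calendar day; empty days count 0.

    Input is expected to be the post-deduplication, post-topic-filter set.
    """
    if not records:
        raise ValueError("daily_engagement requires at least one record")
    df = pd.DataFrame(
        {
            "date": pd.to_datetime([rec.date for rec in records]),
            "user": [rec.user_id for rec in records],
        }
    )
    counts = df.groupby("date")["user"].nunique()
    full = counts.reindex(_date_index(records), fill_value=0).astype(float)
    return DailySeries(values=full, boundary=boundary)
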