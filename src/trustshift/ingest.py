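"""Reading, normalising, deduplicating and period-labelling tweet records.

The corpus arrives as JSONL (one record per line: ``id``, ``timestamp``,
``user_id``, ``text``).  Records are tokenized with a deliberately simple,
fully specified scheme (lowercase, URLs dropped, @-mentions collapsed to a
placeholder, hashtag signs stripped), deduplicated on whitespace-normalised
text, and labelled ``pre``/``post`` relative to the event boundary date.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Placeholder token substituted for @-mentions during tokenization.
MENTION_TOKEN = "<mention>"

#: Two-letter terms of interest exempt from the short-token filter used for
#: LDA / TF-IDF preprocessing.
SHORT_TOKEN_WHITELIST = frozenset({"ob", "phi"})

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"@\w+")
_WORD_RE = re.compile(r"<mention>|[a-z0-9]+")


class MalformedCorpusError(ValueError):
    """Raised when a corpus file has too many unparseable lines."""


@dataclass
class TweetRecord:
    """One post: identifiers, timestamp, raw text, and derived fields."""

    id: str
    timestamp: datetime
    user_id: str
    text: str
    tokens: list[str] | None = None
    period: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("TweetRecord.id must be nonempty")

    @property
    def date(self) -> date:
        """UTC calendar date used for daily binning."""
        return self.timestamp.date()


@dataclass(frozen=True)
class PeriodConfig:
    """Analysis window: records dated on or before ``boundary`` are pre."""

    pre_start: date
    boundary: date
    end: date

    def __post_init__(self) -> None:
        if not (self.pre_start < self.boundary < self.end):
            raise ValueError(
                f"require pre_start < boundary < end, got "
                f"{self.pre_start} / {self.boundary} / {self.end}"
            )


def tokenize(text: str) -> list[str]:
    """Lowercase and split ``text`` into word tokens.

    URLs are removed, @-mentions become :data:`MENTION_TOKEN`, the hashtag
    sign is stripped (the tag word is kept), and the remainder splits on
    anything that is not a lowercase letter or digit.  No length or stop-word
    filtering happens here — embedding training wants full context windows;
    see :func:`filter_tokens` for the LDA/TF-IDF preprocessing.
    """
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(f" {MENTION_TOKEN} ", text)
    text = text.replace("#", " ")
    return _WORD_RE.findall(text)


def filter_tokens(
    tokens: Sequence[str],
    stop_words: Iterable[str] = (),
    min_len: int = 2,
    whitelist: frozenset[str] = SHORT_TOKEN_WHITELIST,
) -> list[str]:
    """Stop-word and short-token filter applied only for LDA and TF-IDF.

    Tokens shorter than ``min_len`` are dropped unless whitelisted ("ob" and
    "phi" are analysis terms of interest).  The mention placeholder is always
    dropped here: it carries no topical content.
    """
    stop = set(stop_words) | {MENTION_TOKEN}
    return [
        t
        for t in tokens
        if t not in stop and (len(t) >= min_len or t in whitelist)
    ]


def read_corpus(
    path: str | Path, max_malformed_frac: float = 0.10
) -> list[TweetRecord]:
    """Read a JSONL corpus, skipping (and counting) malformed lines.

    Raises :class:`MalformedCorpusError` when more than
    ``max_malformed_frac`` of nonempty lines fail to parse, and
    ``FileNotFoundError`` when the file is absent.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    n_bad = 0
    n_lines = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            try:
                obj = json.loads(line)
                records.append(
                    TweetRecord(
                        id=str(obj["id"]),
                        timestamp=datetime.fromisoformat(obj["timestamp"]),
                        user_id=str(obj["user_id"]),
                        text=str(obj["text"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                n_bad += 1
    if n_bad:
        logger.warning("read_corpus: skipped %d malformed line(s) in %s", n_bad, path)
    if n_lines and n_bad / n_lines > max_malformed_frac:
        raise MalformedCorpusError(
            f"{n_bad}/{n_lines} malformed lines exceeds threshold "
            f"{max_malformed_frac:.0%} in {path}"
        )
    return records


def normalize_text(text: str) -> str:
    """Whitespace-collapsed, lowercased text — the deduplication key."""
    return " ".join(text.lower().split())


def deduplicate(records: Sequence[TweetRecord]) -> list[TweetRecord]:
    """Keep the first occurrence (in input order) of each normalised text."""
    seen: set[str] = set()
    out: list[TweetRecord] = []
    for rec in records:
        key = normalize_text(rec.text)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def label_period(rec: TweetRecord, cfg: PeriodConfig) -> TweetRecord:
    """Label one record ``pre``/``post``; raise for out-of-range timestamps."""
    d = rec.date
    if d < cfg.pre_start or d > cfg.end:
        raise ValueError(f"timestamp {rec.timestamp} outside [{cfg.pre_start}, {cfg.end}]")
    rec.period = "pre" if d <= cfg.boundary else "post"
    return rec


def label_periods(
    records: Sequence[TweetRecord], cfg: PeriodConfig
) -> list[TweetRecord]:
    """Label every record, excluding (and logging) out-of-range ones."""
    out: list[TweetRecord] = []
    n_excluded = 0
    for rec in records:
        if rec.date < cfg.pre_start or rec.date > cfg.end:
            n_excluded += 1
            continue
        out.append(label_period(rec, cfg))
    if n_excluded:
        logger.warning("label_periods: excluded %d out-of-range record(s)", n_excluded)
    return out


def tokenize_records(records: Sequence[TweetRecord]) -> list[TweetRecord]:
    """Fill ``tokens`` on every record in place; returns the same list."""
    for rec in records:
        rec.tokens = tokenize(rec.text)
    return list(records)


def export_csv(records: Sequence[TweetRecord], path: str | Path) -> None:
    """Write the deduplicated, labelled corpus as CSV."""
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "date", "user_id", "period", "text"])
        for rec in records:
            writer.writerow([rec.id, rec.date.isoformat(), rec.user_id, rec.period, rec.text])
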