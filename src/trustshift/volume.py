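"""TF-IDF weights, sentiment-split term volumes, and exemplar selection.

The TF-IDF variant is fixed so results are exactly testable: tf is the raw
in-document count and idf(t) = ln(N / df_t) with df_t the number of
documents containing t (unsmoothed, so a term present in every document
weighs zero everywhere).  Term volumes count, per (term, period, polarity),
the tweets whose token set contains the term; for display they are
standardised to z-scores within each polarity panel.  Exemplar tweets for a
term are those at or above a per-term TF-IDF weight quantile, with
URL-carrying tweets excluded (a cheap stand-in for dropping headline/link
posts).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .ingest import TweetRecord
from .sentiment import SentimentResult
from .trust import TermSet

logger = logging.getLogger(__name__)

_URL_IN_TEXT = re.compile(r"(?:https?://|www\.)\S+")


@dataclass
class TfidfMatrix:
    weights: sparse.csr_matrix  # documents x vocabulary
    vocabulary: dict[str, int]

    def term_column(self, term: str) -> np.ndarray:
        j = self.vocabulary[term]
        return np.asarray(self.weights[:, j].todense()).ravel()


def compute_tfidf(docs: Sequence[Sequence[str]]) -> TfidfMatrix:
    """weight(t, d) = count(t in d) * ln(N / df_t)."""
    if not docs:
        raise ValueError("compute_tfidf requires at least one document")
    vocab: dict[str, int] = {}
    rows, cols, tfs = [], [], []
    df_counts: dict[int, int] = {}
    for i, doc in enumerate(docs):
        counts: dict[int, int] = {}
        for tok in doc:
            j = vocab.setdefault(tok, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            tfs.append(c)
            df_counts[j] = df_counts.get(j, 0) + 1
    if not vocab:
        raise ValueError("empty vocabulary: all documents are empty")
    n = len(docs)
    idf = np.empty(len(vocab))
    for j, df in df_counts.items():
        idf[j] = np.log(n / df)
    data = np.asarray(tfs, dtype=float) * idf[np.asarray(cols)]
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, len(vocab)), dtype=float
    )
    return TfidfMatrix(weights=mat, vocabulary=vocab)


def split_by_polarity(
    records: Sequence[TweetRecord], results: Sequence[SentimentResult]
) -> tuple[list[TweetRecord], list[TweetRecord]]:
    """(negative set, positive set); neutral records belong to neither."""
    if len(records) != len(results):
        raise ValueError("records and results must align")
    neg = [r for r, s in zip(records, results) if s.label == "negative"]
    pos = [r for r, s in zip(records, results) if s.label == "positive"]
    return neg, pos


@dataclass
class VolumeTable:
    """Counts and polarity-panel z-scores per (term, period, polarity)."""

    rows: list[dict]  # term, group, period, polarity, count, zscore

    def count(self, term: str, period: str, polarity: str) -> int:
        for r in self.rows:
            if (r["term"], r["period"], r["polarity"]) == (term, period, polarity):
                return r["count"]
        raise KeyError((term, period, polarity))

    def zscore(self, term: str, period: str, polarity: str) -> float:
        for r in self.rows:
            if (r["term"], r["period"], r["polarity"]) == (term, period, polarity):
                return r["zscore"]
        raise KeyError((term, period, polarity))

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "group", "period", "polarity", "count", "zscore"])
            for r in self.rows:
                w.writerow(
                    [r["term"], r["group"], r["period"], r["polarity"],
                     r["count"], f"{r['zscore']:.6f}"]
                )


def volume_table(
    negative: Sequence[TweetRecord],
    positive: Sequence[TweetRecord],
    terms: TermSet,
    periods: Sequence[str] = ("pre", "post"),
) -> VolumeTable:
    """Tweet counts per (term, period, polarity), z-scored per polarity panel.

    Records must be tokenized and period-labelled.  Counts are of tweets
    whose token *set* contains the term.  Within each polarity panel the
    z-scores are computed across all (term, period) cells; a zero-variance
    panel maps to all-zero scores.
    """
    panels = {"negative": negative, "positive": positive}
    token_sets = {
        pol: [set(rec.tokens or ()) for rec in recs] for pol, recs in panels.items()
    }
    rows: list[dict] = []
    for polarity, recs in panels.items():
        cells: list[dict] = []
        for group, group_terms in terms.groups.items():
            for term in group_terms:
                for period in periods:
                    count = sum(
                        1
                        for rec, toks in zip(recs, token_sets[polarity])
                        if rec.period == period and term in toks
                    )
                    cells.append(
                        {
                            "term": term,
                            "group": group,
                            "period": period,
                            "polarity": polarity,
                            "count": count,
                        }
                    )
        values = np.array([c["count"] for c in cells], dtype=float)
        std = values.std()
        if std == 0:
            z = np.zeros_like(values)
        else:
            z = (values - values.mean()) / std
        for c, zi in zip(cells, z):
            c["zscore"] = float(zi)
        rows.extend(cells)
    return VolumeTable(rows=rows)


def select_exemplars(
    tfidf: TfidfMatrix,
    records: Sequence[TweetRecord],
    term: str,
    quantile: float = 0.95,
) -> list[tuple[TweetRecord, float]]:
    """Tweets containing ``term`` at or above the per-term weight quantile.

    Rows of ``tfidf`` must align with ``records``.  Tweets containing URLs
    are excluded regardless of weight; ties at the cutoff are kept.  Returns
    (record, weight) pairs ranked by weight descending.
    """
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    if term not in tfidf.vocabulary:
        logger.warning("select_exemplars: term %r not in vocabulary", term)
        return []
    col = tfidf.term_column(term)
    keep_idx = [
        i
        for i, rec in enumerate(records)
        if col[i] > 0 and not _URL_IN_TEXT.search(rec.text)
    ]
    if not keep_idx:
        return []
    weights = col[keep_idx]
    cutoff = float(np.quantile(weights, quantile))
    survivors = [
        (records[i], float(col[i])) for i in keep_idx if col[i] >= cutoff
    ]
    survivors.sort(key=lambda pair: (-pair[1], pair[0].id))
    return survivors


def export_exemplars(exemplars, term: str, path, append: bool = False) -> None:
    import json

    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for rec, weight in exemplars:
            fh.write(
                json.dumps(
                    {"term": term, "id": rec.id, "weight": weight, "text": rec.text}
                )
                + "\n"
            )
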