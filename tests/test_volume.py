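"""TF-IDF exactness, sentiment splitting, volumes, and exemplar selection."""

import math
from datetime import datetime

import numpy as np
import pytest

from trustshift.ingest import TweetRecord
from trustshift.sentiment import classify
from trustshift.trust import TermSet
from trustshift.volume import (
    compute_tfidf,
    select_exemplars,
    split_by_polarity,
    volume_table,
)


def brute_force_tfidf(docs):
    vocab = sorted({t for d in docs for t in d})
    n = len(docs)
    out = np.zeros((n, len(vocab)))
    for j, term in enumerate(vocab):
        df = sum(1 for d in docs if term in d)
        for i, d in enumerate(docs):
            out[i, j] = d.count(term) * math.log(n / df)
    return vocab, out


def as_dense(tfidf, vocab_order):
    cols = [tfidf.vocabulary[t] for t in vocab_order]
    return np.asarray(tfidf.weights.todense())[:, cols]


class TestComputeTfidf:
    def test_hand_example(self):
        docs = [["a", "b"], ["a"], ["c"]]
        tfidf = compute_tfidf(docs)
        dense = np.asarray(tfidf.weights.todense())
        assert dense[0, tfidf.vocabulary["b"]] == pytest.approx(math.log(3))

    def test_ubiquitous_term_weighs_zero(self):
        docs = [["a", "x"], ["a", "y"], ["a", "a", "z"]]
        tfidf = compute_tfidf(docs)
        col = tfidf.term_column("a")
        np.testing.assert_array_equal(col, 0.0)

    def test_empty_document_row_is_zero(self):
        docs = [["a", "b"], [], ["b"]]
        tfidf = compute_tfidf(docs)
        assert np.asarray(tfidf.weights[1].todense()).sum() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_corpora(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("abcdefgh")
        docs = [
            [alphabet[int(k)] for k in rng.integers(8, size=rng.integers(1, 12))]
            for _ in range(int(rng.integers(2, 50)))
        ]
        vocab, expected = brute_force_tfidf(docs)
        np.testing.assert_allclose(as_dense(compute_tfidf(docs), vocab), expected)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_tfidf([[], []])
        with pytest.raises(ValueError):
            compute_tfidf([])


def _rec(i, text, period="pre", user="u"):
    r = TweetRecord(id=str(i), timestamp=datetime(2022, 5, 1), user_id=user, text=text)
    r.tokens = text.lower().split()
    r.period = period
    return r


def _result(label):
    probs = {"negative": (0.8, 0.1, 0.1), "neutral": (0.1, 0.8, 0.1), "positive": (0.1, 0.1, 0.8)}
    return classify("x", lambda t: probs[label])


class TestSplitByPolarity:
    def test_neutral_excluded_from_both(self):
        recs = [_rec(0, "a"), _rec(1, "b"), _rec(2, "c")]
        results = [_result("negative"), _result("neutral"), _result("positive")]
        neg, pos = split_by_polarity(recs, results)
        assert [r.id for r in neg] == ["0"] and [r.id for r in pos] == ["2"]

    def test_all_neutral_both_empty(self):
        recs = [_rec(i, "x") for i in range(3)]
        neg, pos = split_by_polarity(recs, [_result("neutral")] * 3)
        assert neg == [] and pos == []

    def test_partition_sizes(self, small_corpus):
        from trustshift.sentiment import classify_records

        _, records, _ = small_corpus
        results = classify_records(records)
        neg, pos = split_by_polarity(records, results)
        n_neutral = sum(1 for r in results if r.label == "neutral")
        assert len(neg) + len(pos) == len(records) - n_neutral


class TestVolumeTable:
    terms = TermSet(clinician=("doctor",), health_information=("hipaa",))

    def eight_tweet_corpus(self):
        neg = [
            _rec(0, "doctor visit", "pre"),
            _rec(1, "doctor doctor again", "post"),  # counted once: token-set membership
            _rec(2, "hipaa rules", "post"),
            _rec(3, "nothing here", "post"),
        ]
        pos = [
            _rec(4, "great doctor", "pre"),
            _rec(5, "hipaa helps", "pre"),
            _rec(6, "hipaa helps more", "post"),
            _rec(7, "doctor and hipaa", "post"),
        ]
        return neg, pos

    def test_manual_tally(self):
        neg, pos = self.eight_tweet_corpus()
        table = volume_table(neg, pos, self.terms)
        assert table.count("doctor", "pre", "negative") == 1
        assert table.count("doctor", "post", "negative") == 1
        assert table.count("hipaa", "pre", "negative") == 0
        assert table.count("hipaa", "post", "negative") == 1
        assert table.count("doctor", "pre", "positive") == 1
        assert table.count("hipaa", "post", "positive") == 2

    def test_zscores_standardized_within_panel(self):
        neg, pos = self.eight_tweet_corpus()
        table = volume_table(neg, pos, self.terms)
        for polarity in ("negative", "positive"):
            z = [r["zscore"] for r in table.rows if r["polarity"] == polarity]
            assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
            assert np.std(z) == pytest.approx(1.0, abs=1e-12)

    def test_constant_panel_maps_to_zero(self):
        neg = [_rec(0, "doctor", "pre"), _rec(1, "hipaa", "pre"),
               _rec(2, "doctor", "post"), _rec(3, "hipaa", "post")]
        table = volume_table(neg, [], self.terms)
        for r in table.rows:
            if r["polarity"] == "negative":
                assert r["count"] == 1
            assert r["zscore"] == 0.0

    def test_doubling_post_counts_raises_post_minus_pre_gap(self):
        neg, pos = self.eight_tweet_corpus()
        doubled_neg = neg + [
            _rec(f"{r.id}x", r.text, r.period) for r in neg if r.period == "post"
        ]
        base = volume_table(neg, pos, self.terms)
        doubled = volume_table(doubled_neg, pos, self.terms)
        for term in ("doctor", "hipaa"):
            gap_base = base.zscore(term, "post", "negative") - base.zscore(term, "pre", "negative")
            gap_doubled = doubled.zscore(term, "post", "negative") - doubled.zscore(term, "pre", "negative")
            assert gap_doubled > gap_base

    def test_never_occurring_term_included_with_zero_counts(self):
        neg, pos = self.eight_tweet_corpus()
        terms = TermSet(clinician=("doctor",), health_information=("unseen",))
        table = volume_table(neg, pos, terms)
        assert table.count("unseen", "pre", "negative") == 0
        assert table.count("unseen", "post", "positive") == 0

    def test_order_invariance(self):
        neg, pos = self.eight_tweet_corpus()
        t1 = volume_table(neg, pos, self.terms)
        t2 = volume_table(list(reversed(neg)), list(reversed(pos)), self.terms)
        for r1 in t1.rows:
            assert t2.count(r1["term"], r1["period"], r1["polarity"]) == r1["count"]


class TestSelectExemplars:
    def test_equal_weights_all_survive(self):
        recs = [_rec(i, "term other{}".format(i)) for i in range(6)]
        recs += [_rec(6, "no match"), _rec(7, "none either")]
        tfidf = compute_tfidf([r.tokens for r in recs])
        out = select_exemplars(tfidf, recs, "term", quantile=0.99)
        assert len(out) == 6  # ties at the cut are kept

    def test_top_one_of_twenty_distinct_weights(self):
        # tweet i repeats the term i+1 times -> 20 distinct weights
        recs = [_rec(i, " ".join(["term"] * (i + 1)) + f" pad{i}") for i in range(20)]
        recs.append(_rec(99, "no match here"))
        tfidf = compute_tfidf([r.tokens for r in recs])
        out = select_exemplars(tfidf, recs, "term", quantile=0.95)
        assert [r.id for r, _ in out] == ["19"]

    def test_url_tweets_excluded(self):
        recs = [
            _rec(0, "term term term see http://x.co/page"),
            _rec(1, "term alone"),
        ]
        docs = [["term", "term", "term"], ["term"], ["other"]]
        recs.append(_rec(2, "other"))
        tfidf = compute_tfidf(docs)
        out = select_exemplars(tfidf, recs, "term", quantile=0.5)
        assert [r.id for r, _ in out] == ["1"]

    def test_monotone_nonincreasing_in_quantile(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(30):
            reps = int(rng.integers(1, 6))
            recs.append(_rec(i, " ".join(["term"] * reps) + f" pad{i % 7}"))
        tfidf = compute_tfidf([r.tokens for r in recs])
        sizes = [
            len(select_exemplars(tfidf, recs, "term", quantile=q))
            for q in (0.2, 0.5, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_oov_term_empty_with_warning(self, caplog):
        recs = [_rec(0, "a b")]
        tfidf = compute_tfidf([r.tokens for r in recs])
        with caplog.at_level("WARNING"):
            out = select_exemplars(tfidf, recs, "missing", 0.9)
        assert out == [] and "missing" in caplog.text

    def test_bad_quantile_rejected(self):
        recs = [_rec(0, "a")]
        tfidf = compute_tfidf([r.tokens for r in recs])
        with pytest.raises(ValueError):
            select_exemplars(tfidf, recs, "a", quantile=1.5)
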