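"""Shared fixtures: small synthetic corpora with known ground truth."""

from datetime import date

import pytest

from trustshift.ingest import PeriodConfig, label_periods, tokenize_records
from trustshift.synthetic import CorpusSpec, generate_corpus


def small_spec(seed: int = 7, duplicate_rate: float = 0.2, **overrides) -> CorpusSpec:
    """30 pre days + 20 post days at low intensity: a few hundred tweets."""
    kwargs = dict(
        seed=seed,
        pre_start=date(2022, 3, 1),
        pre_end=date(2022, 3, 30),
        post_start=date(2022, 3, 31),
        post_end=date(2022, 4, 19),
        base_daily_users=8.0,
        engagement_multiplier=2.0,
        tweets_per_user=1.3,
        duplicate_rate=duplicate_rate,
    )
    kwargs.update(overrides)
    return CorpusSpec(**kwargs)


@pytest.fixture(scope="session")
def small_corpus():
    """(spec, records, ground truth) for a corpus with 20% duplicates."""
    spec = small_spec()
    records, gt = generate_corpus(spec)
    return spec, records, gt


@pytest.fixture(scope="session")
def labeled_corpus(small_corpus):
    """Deduplication-free, tokenized, period-labelled view of small_corpus."""
    spec, records, gt = small_corpus
    cfg = PeriodConfig(pre_start=spec.pre_start, boundary=spec.pre_end, end=spec.post_end)
    recs = label_periods(tokenize_records(list(records)), cfg)
    return spec, recs, gt
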