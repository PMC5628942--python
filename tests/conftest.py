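import json
from datetime import datetime, timedelta, timezone

import pytest

from tweetwatch.ingest import Tweet

ONSET = datetime(2016, 2, 7, 18, 30, tzinfo=timezone.utc)


@pytest.fixture
def onset():
    return ONSET


def make_tweet(
    tweet_id="t1",
    seconds=0.0,
    text="hello world",
    user_id="u1",
    follower_count=10,
    is_retweet=False,
    retweeted_id=None,
    retweet_count=0,
    geo=None,
    base=ONSET,
):
    return Tweet(
        tweet_id=tweet_id,
        posted_at=base + timedelta(seconds=seconds),
        text=text,
        user_id=user_id,
        follower_count=follower_count,
        is_retweet=is_retweet,
        retweeted_id=retweeted_id,
        retweet_count=retweet_count,
        geo=geo,
    )


@pytest.fixture
def tweet_factory():
    return make_tweet


def write_ndjson(path, records):
    """Write raw records (dicts or pre-rendered strings) one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec if isinstance(rec, str) else json.dumps(rec))
            fh.write("\n")
    return path


def flat_record(tweet_id="t1", seconds=0.0, base=ONSET, **overrides):
    rec = {
        "id": tweet_id,
        "posted_at": (base + timedelta(seconds=seconds)).isoformat(),
        "text": "hello world",
        "user_id": "u1",
        "follower_count": 10,
    }
    rec.update(overrides)
    return rec
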