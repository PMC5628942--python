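import gzip
import json
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings, strategies as st

from tweetwatch.ingest import (
    ConfigError,
    EventConfig,
    IngestStats,
    MalformedRecord,
    Tweet,
    load_event_config,
    parse_record,
    read_stream,
    read_streams,
    resolve_local,
    resolve_onset,
    write_stream,
)

from conftest import ONSET, flat_record, write_ndjson


class TestReadStream:
    def test_dedupe_and_rate_limit_notice(self, tmp_path):
        path = write_ndjson(
            tmp_path / "s.ndjson",
            [
                flat_record("a", 0),
                flat_record("a", 0),
                {"limit": {"track": 7}},
            ],
        )
        tweets, stats = read_stream(path)
        assert len(tweets) == 1
        assert stats.tweets_kept == 1
        assert stats.duplicates_dropped == 1
        assert stats.rate_limit_notices == 1
        assert stats.rate_limited_missed == 7
        assert stats.balanced

    def test_pre_onset_exclusion(self, tmp_path):
        path = write_ndjson(tmp_path / "s.ndjson", [flat_record("a", -5)])
        tweets, stats = read_stream(path, onset=ONSET)
        assert tweets == []
        assert stats.pre_onset_excluded == 1
        assert stats.balanced

    def test_truncated_records_discarded(self, tmp_path):
        # 251 records: 3 valid, 248 truncated mid-JSON
        records = [flat_record(f"t{i}", i) for i in range(3)]
        lines = [json.dumps(r) for r in records]
        lines += [json.dumps(flat_record(f"x{i}", i))[: 20 + i % 30] for i in range(248)]
        path = write_ndjson(tmp_path / "s.ndjson", lines)
        tweets, stats = read_stream(path)
        assert len(tweets) == 3
        assert stats.records_read == 251
        assert stats.malformed_discarded == 248
        assert stats.balanced

    def test_valid_json_but_not_a_tweet_is_malformed(self, tmp_path):
        path = write_ndjson(tmp_path / "s.ndjson", [{"hello": "world"}])
        tweets, stats = read_stream(path)
        assert tweets == [] and stats.malformed_discarded == 1

    def test_naive_timestamp_is_malformed(self, tmp_path):
        rec = flat_record("a", 0, posted_at="2016-02-07T18:30:00")
        path = write_ndjson(tmp_path / "s.ndjson", [rec])
        _, stats = read_stream(path)
        assert stats.malformed_discarded == 1

    def test_unordered_input_stably_sorted(self, tmp_path):
        recs = [flat_record("b", 60), flat_record("a", 0), flat_record("c", 60)]
        path = write_ndjson(tmp_path / "s.ndjson", recs)
        tweets, _ = read_stream(path)
        assert [t.tweet_id for t in tweets] == ["a", "b", "c"]  # ties keep input order

    def test_gzip_detected_by_magic(self, tmp_path):
        path = tmp_path / "s.ndjson.gz"
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(json.dumps(flat_record("a", 0)) + "\n")
        tweets, stats = read_stream(path)
        assert len(tweets) == 1 and stats.tweets_kept == 1

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(OSError):
            read_stream(tmp_path / "nope.ndjson")

    def test_empty_lines_not_counted(self, tmp_path):
        path = tmp_path / "s.ndjson"
        path.write_text("\n" + json.dumps(flat_record("a", 0)) + "\n\n")
        _, stats = read_stream(path)
        assert stats.records_read == 1

    def test_cross_file_dedupe(self, tmp_path):
        p1 = write_ndjson(tmp_path / "a.ndjson", [flat_record("a", 0)])
        p2 = write_ndjson(tmp_path / "b.ndjson", [flat_record("a", 0), flat_record("b", 5)])
        tweets, stats = read_streams([p1, p2])
        assert [t.tweet_id for t in tweets] == ["a", "b"]
        assert stats.duplicates_dropped == 1 and stats.balanced


class TestActivityDialect:
    def test_share_verb_marks_retweet(self):
        tweet = parse_record(
            {
                "id": "tag:1",
                "verb": "share",
                "postedTime": "2016-02-07T18:30:00.000Z",
                "body": "RT @x: hi",
                "actor": {"id": "user:9", "followersCount": 42},
                "object": {"id": "tag:0"},
                "retweetCount": 3,
            }
        )
        assert tweet.is_retweet and tweet.retweeted_id == "tag:0"
        assert tweet.follower_count == 42 and tweet.retweet_count == 3

    def test_rt_prefix_convention(self):
        tweet = parse_record(flat_record("a", 0, text="RT @cnn: breaking"))
        assert tweet.is_retweet


class TestResolveOnset:
    def test_pdt(self):
        utc = resolve_local(datetime(2014, 8, 24, 3, 20, 44), "America/Los_Angeles")
        assert utc == datetime(2014, 8, 24, 10, 20, 44, tzinfo=timezone.utc)

    def test_est(self):
        utc = resolve_local(datetime(2012, 12, 14, 9, 35, 0), "America/New_York")
        assert utc == datetime(2012, 12, 14, 14, 35, 0, tzinfo=timezone.utc)

    def test_spring_forward_gap_rejected(self):
        with pytest.raises(ConfigError, match="does not exist"):
            resolve_local(datetime(2015, 3, 8, 2, 30), "America/Los_Angeles")

    def test_ambiguous_fold_rejected_naming_candidates(self):
        with pytest.raises(ConfigError, match="08:30.*09:30"):
            resolve_local(datetime(2014, 11, 2, 1, 30), "America/Los_Angeles")

    def test_unknown_timezone(self):
        with pytest.raises(ConfigError, match="unknown timezone"):
            resolve_local(datetime(2014, 1, 1), "Mars/Olympus")

    def test_resolve_onset_from_config(self):
        config = EventConfig(
            name="ne", onset_local=datetime(2014, 8, 24, 3, 20, 44), tz="America/Los_Angeles"
        )
        assert resolve_onset(config) == datetime(2014, 8, 24, 10, 20, 44, tzinfo=timezone.utc)


class TestEventConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "event.yaml"
        path.write_text(
            "name: ne\n"
            "onset: 2014-08-24 03:20:44\n"
            "timezone: America/Los_Angeles\n"
            "horizon_minutes: 720\n"
            "rules:\n"
            "  - \"Earthquake (San Francisco OR 'sf' OR Napa OR '6.0')\"\n"
            "timeline:\n"
            "  first_911_call: 2014-08-24 03:21:30\n"
            "  county_disaster_page: 2014-08-24T10:40:00Z\n"
        )
        config = load_event_config(path)
        assert config.name == "ne" and len(config.rules) == 1
        assert config.timeline["first_911_call"] == datetime(
            2014, 8, 24, 10, 21, 30, tzinfo=timezone.utc
        )
        assert config.timeline["county_disaster_page"] == datetime(
            2014, 8, 24, 10, 40, tzinfo=timezone.utc
        )

    def test_timeline_sanity_bound(self, tmp_path):
        path = tmp_path / "event.yaml"
        path.write_text(
            "name: x\nonset: 2014-08-24 03:20:44\ntimezone: America/Los_Angeles\n"
            "timeline:\n  other: 2014-08-20T00:00:00Z\n"
        )
        with pytest.raises(ConfigError, match="24h before onset"):
            load_event_config(path)

    def test_nonpositive_horizon(self):
        with pytest.raises(ConfigError):
            EventConfig(name="x", onset_local=datetime(2014, 1, 1), tz="UTC", horizon_minutes=0)


# -- properties -------------------------------------------------------------

tweet_strategy = st.builds(
    Tweet,
    tweet_id=st.uuids().map(str),
    posted_at=st.datetimes(
        min_value=datetime(2012, 1, 1),
        max_value=datetime(2020, 1, 1),
    ).map(lambda d: d.replace(tzinfo=timezone.utc)),
    text=st.text(max_size=60).filter(lambda s: not s.startswith("RT @")),
    user_id=st.text(alphabet="abcdef0123456789", min_size=1, max_size=8),
    follower_count=st.integers(min_value=0, max_value=10**7),
    is_retweet=st.just(False),
    retweeted_id=st.none(),
    retweet_count=st.integers(min_value=0, max_value=10**4),
    geo=st.none() | st.tuples(
        st.floats(min_value=-90, max_value=90, allow_nan=False),
        st.floats(min_value=-180, max_value=180, allow_nan=False),
    ),
)


@settings(max_examples=50, deadline=None)
@given(st.lists(tweet_strategy, max_size=20, unique_by=lambda t: t.tweet_id))
def test_round_trip_identity(tmp_path_factory, tweets):
    path = tmp_path_factory.mktemp("rt") / "s.ndjson"
    tweets = sorted(tweets, key=lambda t: t.posted_at)
    write_stream(tweets, path)
    back, stats = read_stream(path)
    assert back == tweets
    assert stats.malformed_discarded == 0 and stats.duplicates_dropped == 0
    assert stats.tweets_kept == len(tweets) and stats.balanced


def test_idempotent_reclean(tmp_path):
    path = write_ndjson(
        tmp_path / "s.ndjson",
        [flat_record("a", 3), flat_record("a", 3), {"limit": {"track": 2}}, "not json"],
    )
    tweets, _ = read_stream(path)
    cleaned = tmp_path / "clean.ndjson"
    write_stream(tweets, cleaned)
    again, stats = read_stream(cleaned)
    assert again == tweets
    assert stats.records_read == stats.tweets_kept == len(tweets)


corrupt_line = st.one_of(
    st.text(max_size=30),  # garbage
    st.builds(lambda i: json.dumps(flat_record(f"id{i}", i)), st.integers(0, 5)),  # valid/dup
    st.builds(lambda n: json.dumps({"limit": {"track": n}}), st.integers(0, 100)),  # notice
    st.builds(
        lambda i: json.dumps(flat_record(f"pre{i}", -1 - i)), st.integers(0, 5)
    ),  # pre-onset
    st.builds(lambda r: json.dumps(r)[:15], st.builds(lambda: flat_record("x", 0))),  # truncated
)


@settings(max_examples=100, deadline=None)
@given(st.lists(corrupt_line, max_size=30))
def test_ledger_equation_under_corruption(tmp_path_factory, lines):
    path = tmp_path_factory.mktemp("fz") / "s.ndjson"
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line.replace("\n", " ") + "\n")
    tweets, stats = read_stream(path, onset=ONSET)
    assert stats.balanced
    assert stats.tweets_kept == len(tweets)
    assert all(getattr(stats, f) >= 0 for f in vars(stats))
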