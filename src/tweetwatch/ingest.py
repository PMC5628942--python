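"""Reading, cleaning and validating newline-delimited JSON tweet streams.

Two input dialects are accepted per line:

* the canonical flat schema (see README): ``id``, ``posted_at``
  (ISO-8601 with explicit UTC offset or trailing ``Z``), ``text``,
  ``user_id``, ``follower_count``, optional ``is_retweet``,
  ``retweeted_id``, ``retweet_count`` and ``geo`` ``[lat, lon]``;
* a best-effort activity-stream adapter (``postedTime``, ``body``,
  ``actor.id``/``actor.followersCount``, ``verb == "share"`` marking a
  repost of ``object.id``).

A rate-limit notice is a JSON object whose payload is a ``limit``
object carrying the integer number of withheld messages; notices yield
no tweets but are tallied.  Records that are not valid JSON, lack a
required field, or carry a naive timestamp are counted as malformed and
skipped — naive local times would silently corrupt onset-anchored
binning, so they are rejected rather than guessed at.

Gzip-compressed input is detected by magic bytes and decompressed
transparently.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence
from zoneinfo import ZoneInfo, ZoneInfoNotFoundError

import yaml

from . import rules as _rules

__all__ = [
    "Tweet",
    "IngestStats",
    "EventConfig",
    "ConfigError",
    "MalformedRecord",
    "read_stream",
    "read_streams",
    "write_stream",
    "resolve_local",
    "resolve_onset",
    "load_event_config",
]

log = logging.getLogger(__name__)

RETWEET_PREFIX = "RT @"


class ConfigError(ValueError):
    """Invalid event configuration (timezone, onset, horizon...)."""


class MalformedRecord(ValueError):
    """A JSON line that cannot be interpreted as a tweet or notice."""


@dataclass
class Tweet:
    """One posted message with timing, author and repost metadata."""

    tweet_id: str
    posted_at: datetime  # timezone-aware, stored in UTC
    text: str
    user_id: str
    follower_count: int
    is_retweet: bool = False
    retweeted_id: Optional[str] = None
    retweet_count: int = 0
    geo: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.tweet_id:
            raise MalformedRecord("empty tweet id")
        if self.posted_at.tzinfo is None:
            raise MalformedRecord("naive timestamp")
        self.posted_at = self.posted_at.astimezone(timezone.utc)
        if self.follower_count < 0 or self.retweet_count < 0:
            raise MalformedRecord("negative count")
        if self.retweeted_id is not None or self.text.startswith(RETWEET_PREFIX):
            self.is_retweet = True

    def to_record(self) -> dict:
        rec = {
            "id": self.tweet_id,
            "posted_at": self.posted_at.isoformat().replace("+00:00", "Z"),
            "text": self.text,
            "user_id": self.user_id,
            "follower_count": self.follower_count,
            "is_retweet": self.is_retweet,
            "retweet_count": self.retweet_count,
        }
        if self.retweeted_id is not None:
            rec["retweeted_id"] = self.retweeted_id
        if self.geo is not None:
            rec["geo"] = [self.geo[0], self.geo[1]]
        return rec


def _parse_instant(value) -> datetime:
    if not isinstance(value, str):
        raise MalformedRecord(f"timestamp not a string: {value!r}")
    try:
        dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError as exc:
        raise MalformedRecord(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        raise MalformedRecord(f"naive timestamp {value!r}")
    return dt.astimezone(timezone.utc)


def _tweet_from_flat(obj: dict) -> Tweet:
    try:
        tweet_id = obj["id"]
        posted_at = _parse_instant(obj["posted_at"])
        text = obj["text"]
        user_id = obj["user_id"]
        follower_count = obj["follower_count"]
    except KeyError as exc:
        raise MalformedRecord(f"missing required field {exc}") from exc
    if not isinstance(text, str) or not isinstance(follower_count, int):
        raise MalformedRecord("wrong field type")
    geo = obj.get("geo")
    return Tweet(
        tweet_id=str(tweet_id),
        posted_at=posted_at,
        text=text,
        user_id=str(user_id),
        follower_count=follower_count,
        is_retweet=bool(obj.get("is_retweet", False)),
        retweeted_id=None if obj.get("retweeted_id") is None else str(obj["retweeted_id"]),
        retweet_count=int(obj.get("retweet_count", 0)),
        geo=None if geo is None else (float(geo[0]), float(geo[1])),
    )


def _tweet_from_activity(obj: dict) -> Tweet:
    """Best-effort mapping of the activity-stream dialect."""
    try:
        actor = obj["actor"]
        tweet_id = obj["id"]
        posted_at = _parse_instant(obj["postedTime"])
        text = obj["body"]
        user_id = actor["id"]
        follower_count = actor["followersCount"]
    except (KeyError, TypeError) as exc:
        raise MalformedRecord(f"missing activity field: {exc}") from exc
    if not isinstance(text, str) or not isinstance(follower_count, int):
        raise MalformedRecord("wrong field type")
    is_share = obj.get("verb") == "share"
    retweeted_id = None
    if is_share:
        retweeted_id = (obj.get("object") or {}).get("id")
    return Tweet(
        tweet_id=str(tweet_id),
        posted_at=posted_at,
        text=text,
        user_id=str(user_id),
        follower_count=follower_count,
        is_retweet=is_share,
        retweeted_id=None if retweeted_id is None else str(retweeted_id),
        retweet_count=int(obj.get("retweetCount", 0)),
    )


def parse_record(obj: dict) -> Tweet:
    """Interpret one decoded JSON object as a Tweet (either dialect)."""
    if not isinstance(obj, dict):
        raise MalformedRecord("record is not a JSON object")
    if "actor" in obj or "postedTime" in obj:
        return _tweet_from_activity(obj)
    return _tweet_from_flat(obj)


def _rate_limit_missed(obj) -> Optional[int]:
    """Missed-message count if *obj* is a rate-limit notice, else None."""
    if not isinstance(obj, dict) or "limit" not in obj:
        return None
    payload = obj["limit"]
    if isinstance(payload, dict):
        for key in ("track", "missed", "count"):
            if isinstance(payload.get(key), int):
                return payload[key]
        return None
    if isinstance(payload, int):
        return payload
    return None


@dataclass
class IngestStats:
    """Per-stream bookkeeping; every input record lands in exactly one
    bucket, so ``records_read`` always equals the bucket sum."""

    records_read: int = 0
    tweets_kept: int = 0
    duplicates_dropped: int = 0
    malformed_discarded: int = 0
    rate_limit_notices: int = 0
    rate_limited_missed: int = 0
    pre_onset_excluded: int = 0

    @property
    def balanced(self) -> bool:
        return self.records_read == (
            self.tweets_kept
            + self.duplicates_dropped
            + self.malformed_discarded
            + self.rate_limit_notices
            + self.pre_onset_excluded
        )

    def merge(self, other: "IngestStats") -> "IngestStats":
        return IngestStats(
            *(getattr(self, f) + getattr(other, f) for f in (
                "records_read", "tweets_kept", "duplicates_dropped",
                "malformed_discarded", "rate_limit_notices",
                "rate_limited_missed", "pre_onset_excluded",
            ))
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _open_text(path) -> io.TextIOBase:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="utf-8")
    return io.TextIOWrapper(fh, encoding="utf-8")


def read_stream(
    path,
    onset: Optional[datetime] = None,
    seen_ids: Optional[set] = None,
) -> tuple[list[Tweet], IngestStats]:
    """Read one NDJSON stream file, returning cleaned tweets and stats.

    Tweets come back in non-decreasing ``posted_at`` order (stable with
    respect to input order); duplicates by id keep the first occurrence;
    tweets earlier than *onset* (when given) are excluded and counted.
    *seen_ids* lets callers deduplicate across several files.
    """
    stats = IngestStats()
    tweets: list[Tweet] = []
    seen = seen_ids if seen_ids is not None else set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            stats.records_read += 1
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                stats.malformed_discarded += 1
                log.debug("%s:%d: invalid JSON", path, lineno)
                continue
            missed = _rate_limit_missed(obj)
            if missed is not None:
                stats.rate_limit_notices += 1
                stats.rate_limited_missed += missed
                continue
            try:
                tweet = parse_record(obj)
            except MalformedRecord as exc:
                stats.malformed_discarded += 1
                log.debug("%s:%d: %s", path, lineno, exc)
                continue
            if tweet.tweet_id in seen:
                stats.duplicates_dropped += 1
                continue
            seen.add(tweet.tweet_id)
            if onset is not None and tweet.posted_at < onset:
                stats.pre_onset_excluded += 1
                continue
            stats.tweets_kept += 1
            tweets.append(tweet)
    tweets.sort(key=lambda t: t.posted_at)  # stable: ties keep input order
    return tweets, stats


def read_streams(paths, onset: Optional[datetime] = None) -> tuple[list[Tweet], IngestStats]:
    """Read and merge several stream files, deduplicating across files."""
    seen: set = set()
    total = IngestStats()
    merged: list[Tweet] = []
    for path in paths:
        tweets, stats = read_stream(path, onset=onset, seen_ids=seen)
        merged.extend(tweets)
        total = total.merge(stats)
    merged.sort(key=lambda t: t.posted_at)
    return merged, total


def write_stream(tweets: Sequence[Tweet], path) -> None:
    """Write tweets as flat-schema NDJSON (one object per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tweet in tweets:
            fh.write(json.dumps(tweet.to_record(), ensure_ascii=False))
            fh.write("\n")


# --------------------------------------------------------------------------
# Event configuration


@dataclass
class EventConfig:
    """An event's onset, filter rules and notification timeline."""

    name: str
    onset_local: datetime  # naive civil time in `tz`
    tz: str
    rules: list = field(default_factory=list)
    horizon_minutes: int = 720
    timeline: dict[str, datetime] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon_minutes <= 0:
            raise ConfigError("horizon_minutes must be positive")


def resolve_local(naive: datetime, tz_name: str) -> datetime:
    """Resolve a naive civil time in an IANA zone to its unique UTC instant.

    Ambiguous (fall-back) and nonexistent (spring-forward) local times
    are configuration errors, not guesses.
    """
    if naive.tzinfo is not None:
        return naive.astimezone(timezone.utc)
    try:
        tz = ZoneInfo(tz_name)
    except (ZoneInfoNotFoundError, ValueError) as exc:
        raise ConfigError(f"unknown timezone {tz_name!r}") from exc
    early = naive.replace(tzinfo=tz, fold=0)
    late = naive.replace(tzinfo=tz, fold=1)
    if early.utcoffset() != late.utcoffset():
        round_trip = early.astimezone(timezone.utc).astimezone(tz).replace(tzinfo=None)
        if round_trip != naive:
            raise ConfigError(
                f"local time {naive.isoformat()} does not exist in {tz_name} (DST gap)"
            )
        raise ConfigError(
            f"local time {naive.isoformat()} is ambiguous in {tz_name}: "
            f"{early.astimezone(timezone.utc).isoformat()} or "
            f"{late.astimezone(timezone.utc).isoformat()}"
        )
    return early.astimezone(timezone.utc)


def resolve_onset(config: EventConfig) -> datetime:
    """UTC instant of the configured local onset."""
    return resolve_local(config.onset_local, config.tz)


def _parse_config_instant(value, tz_name: str) -> datetime:
    if isinstance(value, datetime):
        return value.astimezone(timezone.utc) if value.tzinfo else resolve_local(value, tz_name)
    dt = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if dt.tzinfo is None:
        return resolve_local(dt, tz_name)
    return dt.astimezone(timezone.utc)


def load_event_config(path) -> EventConfig:
    """Load an EventConfig from YAML or JSON.

    Keys: ``name``, ``onset`` (local civil time), ``timezone`` (IANA
    name), ``rules`` (list of rule strings), ``horizon_minutes``
    (default 720), ``timeline`` (mark name -> instant; naive values are
    interpreted in the event timezone).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    try:
        name = raw["name"]
        onset_raw = raw["onset"]
        tz_name = raw["timezone"]
    except KeyError as exc:
        raise ConfigError(f"config missing key {exc}") from exc
    if isinstance(onset_raw, datetime):
        onset_local = onset_raw
    else:
        try:
            onset_local = datetime.fromisoformat(str(onset_raw))
        except ValueError as exc:
            raise ConfigError(f"unparseable onset {onset_raw!r}") from exc
    rules = [_rules.parse_rule(r) for r in (raw.get("rules") or [])]
    config = EventConfig(
        name=str(name),
        onset_local=onset_local,
        tz=str(tz_name),
        rules=rules,
        horizon_minutes=int(raw.get("horizon_minutes", 720)),
    )
    onset_utc = resolve_onset(config)
    for mark, value in (raw.get("timeline") or {}).items():
        instant = _parse_config_instant(value, tz_name)
        if instant < onset_utc - timedelta(hours=24):
            raise ConfigError(
                f"timeline mark {mark!r} at {instant.isoformat()} is more than "
                f"24h before onset {onset_utc.isoformat()}"
            )
        config.timeline[str(mark)] = instant
    return config
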